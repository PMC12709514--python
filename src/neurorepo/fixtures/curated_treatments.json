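{
  "description": "Curated treatments layer: 29 literature-extracted interventions for neuroinflammation-linked ASD in children, with component compounds, curated action keywords and reported effects. Identifiers elsewhere in the bundle are synthetic placeholders, not real accessions.",
  "treatments": [
    {
      "label": "Methylphenidate",
      "components": ["Methylphenidate"],
      "effects": ["reduction in ADHD-like symptoms"]
    },
    {
      "label": "Memantine",
      "components": ["Memantine"],
      "effects": ["improvements in social interaction", "improvements in communication"]
    },
    {
      "label": "Atomoxetine",
      "components": ["Atomoxetine"],
      "effects": ["reduction in hyperactivity"]
    },
    {
      "label": "Fluoxetine+cyamemazine+valproic acid",
      "components": ["Fluoxetine", "Cyamemazine", "Valproic acid"],
      "effects": ["reduced anxiety", "improvements in social interaction", "decreases in self-injurious behavior"]
    },
    {
      "label": "Fluoxetine+risperidone+loxapine",
      "components": ["Fluoxetine", "Risperidone", "Loxapine"],
      "effects": ["improvements in social interaction", "reduced aggressive behaviors", "decreases in risperidone dosages"]
    },
    {
      "label": "Fluoxetine+risperidone",
      "components": ["Fluoxetine", "Risperidone"],
      "effects": ["improvements in social interaction"]
    },
    {
      "label": "Fluoxetine+risperidone+melatonin",
      "components": ["Fluoxetine", "Risperidone", "Melatonin"],
      "effects": ["improvements in social interaction", "reductions in anxiety", "decreases in ADHD-like symptoms"]
    },
    {
      "label": "Controlled-release melatonin",
      "components": ["Melatonin"],
      "effects": ["improved sleep"]
    },
    {
      "label": "N-acetylcysteine",
      "components": ["Acetylcysteine"],
      "synonyms": {"Acetylcysteine": ["N-acetylcysteine", "NAC"]},
      "effects": ["reduced irritability"]
    },
    {
      "label": "Buspirone",
      "components": ["Buspirone"],
      "effects": ["reduced anxiety"]
    },
    {
      "label": "Intranasal oxytocin",
      "components": ["Oxytocin"],
      "effects": ["improvements in social interaction"]
    },
    {
      "label": "Vitamin D3",
      "components": ["Vitamin D3"],
      "synonyms": {"Vitamin D3": ["Cholecalciferol"]},
      "effects": ["reduced irritability"]
    },
    {
      "label": "DHA; an omega-3 fatty acid",
      "components": ["Doconexent"],
      "synonyms": {"Doconexent": ["DHA", "Docosahexaenoic acid"]},
      "effects": ["improvements in hyperactivity"]
    },
    {
      "label": "Vitamin D3+DHA",
      "components": ["Vitamin D3", "Doconexent"],
      "effects": ["reduced irritability and hyperactivity"]
    },
    {
      "label": "Cannabidiol",
      "components": ["Cannabidiol"],
      "effects": ["reduced anxiety", "reduced psychomotor agitation", "improvements in social interaction", "increased number of daily meals", "enhanced concentration"]
    },
    {
      "label": "Sulforaphane+risperidone",
      "components": ["Sulforaphane", "Risperidone"],
      "keywords": {
        "Sulforaphane": [
          "upregulating antioxidants",
          "activating nuclear factor erythroid 2-related factor 2",
          "inhibiting nuclear factor kappa B",
          "enhancing extracellular signal-regulated kinase",
          "increasing neuronal autophagy flux",
          "reducing interleukin 6/tumor necrosis factor alpha and interleukin 1 beta"
        ],
        "Risperidone": [
          "inhibiting D2 dopaminergic receptors",
          "reducing dopaminergic neurotransmission"
        ]
      },
      "effects": ["improvements in irritability and hyperactivity/noncompliance"]
    },
    {
      "label": "Sulforaphane",
      "components": ["Sulforaphane"],
      "effects": ["improvements in social responsiveness"]
    },
    {
      "label": "Memantine+risperidone",
      "components": ["Memantine", "Risperidone"],
      "effects": ["reductions in irritability", "reductions in stereotypic behavior", "reductions in hyperactivity"]
    },
    {
      "label": "Prednisolone",
      "components": ["Prednisolone"],
      "effects": ["improved language function"]
    },
    {
      "label": "Bumetanide",
      "components": ["Bumetanide"],
      "effects": ["reduced ASD severity scores"]
    },
    {
      "label": "Ketogenic diet+modified Atkins diet+low glycemic index treatments",
      "components": ["Ketogenic diet", "Modified Atkins diet", "Low glycemic index treatments"],
      "effects": ["behavioral improvements"]
    },
    {
      "label": "Ubiquinol",
      "components": ["Ubidecarenone"],
      "synonyms": {"Ubidecarenone": ["Ubiquinol", "Coenzyme Q10"]},
      "effects": ["improved communication"]
    },
    {
      "label": "adrenal corticosteroid",
      "components": ["Prednisolone"],
      "effects": ["improved language function"]
    },
    {
      "label": "Luteolin",
      "components": ["Luteolin"],
      "effects": ["improved adaptive functioning"]
    },
    {
      "label": "Umbilical cord blood infusion",
      "components": ["Umbilical cord blood cells"],
      "effects": ["behavioral improvements"]
    },
    {
      "label": "Chondroitin sulfate+phosphatidylcholine+vitamin D3",
      "components": ["Chondroitin sulfate", "Lecithin", "Vitamin D3"],
      "synonyms": {"Lecithin": ["Phosphatidylcholine"]},
      "effects": ["behavioral improvements"]
    },
    {
      "label": "High protease pancreatic therapy",
      "components": ["High-protease pancreatic enzyme"],
      "effects": ["behavioral improvements"]
    },
    {
      "label": "Single infusion of autologous umbilical cord blood",
      "components": ["Autologous umbilical cord blood"],
      "effects": ["behavioral improvements"]
    },
    {
      "label": "Autologous bone marrow mononuclear cells",
      "components": ["Autologous bone marrow mononuclear cells"],
      "effects": ["behavioral improvements"]
    }
  ]
}
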