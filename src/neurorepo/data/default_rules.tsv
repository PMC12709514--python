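pattern	pathway	provenance
antioxidant	oxidative_stress	Sies H (2015) Oxidative stress: a concept in redox biology. Redox Biol 4:180-183
nuclear factor erythroid 2-related factor 2	oxidative_stress	Ma Q (2013) Role of Nrf2 in oxidative stress and toxicity. Annu Rev Pharmacol Toxicol 53:401-426
nrf2	oxidative_stress	Ma Q (2013) Role of Nrf2 in oxidative stress and toxicity. Annu Rev Pharmacol Toxicol 53:401-426
nuclear factor kappa b	inflammation	Liu T et al (2017) NF-kB signaling in inflammation. Signal Transduct Target Ther 2:17023
nf-kb	inflammation	Liu T et al (2017) NF-kB signaling in inflammation. Signal Transduct Target Ther 2:17023
extracellular signal-regulated kinase	neurotransmitter_regulation	Thomas GM, Huganir RL (2004) MAPK cascade signalling and synaptic plasticity. Nat Rev Neurosci 5:173-183
interleukin	inflammation	Dinarello CA (2000) Proinflammatory cytokines. Chest 118:503-508
interleukin	immune_system	Dinarello CA (2000) Proinflammatory cytokines. Chest 118:503-508
tumor necrosis factor	inflammation	Bradley JR (2008) TNF-mediated inflammatory disease. J Pathol 214:149-160
tumor necrosis factor	immune_system	Bradley JR (2008) TNF-mediated inflammatory disease. J Pathol 214:149-160
cytokine	inflammation	Dinarello CA (2000) Proinflammatory cytokines. Chest 118:503-508
cytokine	immune_system	Dinarello CA (2000) Proinflammatory cytokines. Chest 118:503-508
dopaminergic	neurotransmitter_regulation	Seeman P (2002) Atypical antipsychotics: mechanism of action. Can J Psychiatry 47:27-38
serotonergic	neurotransmitter_regulation	Berger M et al (2009) The expanded biology of serotonin. Annu Rev Med 60:355-366
serotonin reuptake	neurotransmitter_regulation	Berger M et al (2009) The expanded biology of serotonin. Annu Rev Med 60:355-366
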