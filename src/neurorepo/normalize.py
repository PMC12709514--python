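"""Name normalization shared by every module.

Drug, category, target and pathway names from heterogeneous sources are
matched by a *normalized* form: lowercase, internal whitespace collapsed,
and spaces adjacent to punctuation removed (so "5-methoxy-N, N-dimethyl..."
and "5-methoxy-N,N-dimethyl..." collide as intended).  Greek letters and
hyphens are preserved — they are semantically load-bearing in protein names.
"""

from __future__ import annotations

import hashlib
import re

_WS = re.compile(r"\s+")
_PUNCT_SPACE = re.compile(r"\s*([,;:/()+])\s*")


def normalize_name(name: str) -> str:
    """Return the canonical matching key for an entity name.

    Raises ``ValueError`` on empty or whitespace-only input.
    """
    if name is None or not name.strip():
        raise ValueError("name must be non-empty")
    s = _WS.sub(" ", name.strip().lower())
    s = _PUNCT_SPACE.sub(r"\1", s)
    return s


def local_id(prefix: str, name: str) -> str:
    """Deterministic local identifier derived from the normalized name.

    Stable across runs and processes (no hash randomization): used when an
    entity carries no DrugBank/SMPDB-style accession.
    """
    digest = hashlib.sha1(normalize_name(name).encode("utf-8")).hexdigest()[:10]
    return f"{prefix}-{digest}"


class Normalizer:
    """Configurable normalization policy (all toggles default on).

    ``casefold``: lowercase before matching; ``collapse_whitespace``:
    fold runs of whitespace to one space; ``collapse_punctuation_spaces``:
    drop spaces next to separator punctuation.
    """

    def __init__(
        self,
        casefold: bool = True,
        collapse_whitespace: bool = True,
        collapse_punctuation_spaces: bool = True,
    ) -> None:
        self.casefold = casefold
        self.collapse_whitespace = collapse_whitespace
        self.collapse_punctuation_spaces = collapse_punctuation_spaces

    def __call__(self, name: str) -> str:
        if name is None or not name.strip():
            raise ValueError("name must be non-empty")
        s = name.strip()
        if self.casefold:
            s = s.lower()
        if self.collapse_whitespace:
            s = _WS.sub(" ", s)
        if self.collapse_punctuation_spaces:
            s = _PUNCT_SPACE.sub(r"\1", s)
        return s


_DRUGBANK_ID = re.compile(r"^DB\d{5}$")
_SMPDB_ID = re.compile(r"^SMP\d{5}$")


def is_drugbank_id(s: str) -> bool:
    return bool(_DRUGBANK_ID.match(s or ""))


def is_smpdb_id(s: str) -> bool:
    return bool(_SMPDB_ID.match(s or ""))
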