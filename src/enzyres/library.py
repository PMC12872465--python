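"""The reference enzyme and peptide library of the reservoir design.

Seven catalysts — six proteases (trypsin, chymotrypsin, elastase,
thrombin, thermolysin, prolyl endopeptidase) and alkaline phosphatase —
act on seven short peptides.  Three peptides are slow substrates that
behave as effective reversible inhibitors of a specific protease
(CCFSWRCRC for chymotrypsin, IYPFVEPI for prolyl endopeptidase, TKIFKI
for trypsin), and CCF(pS)WRCRC is a phosphorylated proinhibitor whose
chymotrypsin-inhibiting form is released by alkaline phosphatase.

The four peptides above are the published sequences.  Peptides "1", "2"
and "6" are SYNTHETIC stand-ins designed to carry multiple cleavage
sites for two or more proteases each (peptide 6 contains the classic
thrombin recognition motif LVPR/GS); swap in real sequences via
:func:`make_peptides` if they are known.

Protease specificities are data, not code: the defaults below use the
canonical rules, and :func:`load_specificity_config` reads a YAML file
mapping enzyme names to rule strings (``after:KR except_before:P`` /
``before:ILVFMA``) so the chemistry assumptions stay auditable and
swappable.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import yaml

from .network import CleavageRule, Enzyme
from .peptides import Peptide

#: canonical specificity table (rule strings)
DEFAULT_SPECIFICITY: dict[str, list[str]] = {
    "trypsin": ["after:KR except_before:P"],
    "chymotrypsin": ["after:FWY except_before:P"],
    "elastase": ["after:AVGS except_before:P"],
    "thrombin": ["after:R"],  # narrowed to R|G context below
    "thermolysin": ["before:ILVFMA"],
    "prolyl_endopeptidase": ["after:P"],
}

ALKALINE_PHOSPHATASE = "alkaline_phosphatase"

#: slow-substrate pairs: intact peptide sequence -> enzyme it inhibits
SLOW_SUBSTRATE_PAIRS: dict[str, str] = {
    "CCFSWRCRC": "chymotrypsin",
    "IYPFVEPI": "prolyl_endopeptidase",
    "TKIFKI": "trypsin",
}

_PEPTIDE_SEQUENCES: dict[str, str] = {
    "1": "AYKGFAVLR",      # synthetic stand-in
    "2": "WGPEFRGS",       # synthetic stand-in
    "3": "CCFSWRCRC",
    "4": "CCF(pS)WRCRC",
    "5": "IYPFVEPI",
    "6": "LVPRGSAK",       # synthetic stand-in (thrombin motif LVPR/GS)
    "7": "TKIFKI",
}


def _thrombin_rule() -> CleavageRule:
    # expressed with the generic machinery: after R, except before anything
    # that is not G
    not_g = frozenset("ACDEFHIKLMNPQRSTVWY") | frozenset(["pS"])
    return CleavageRule(kind="after", residues=frozenset("R"), except_before=not_g)


def make_enzymes(
    names: Sequence[str] | None = None,
    specificity: Mapping[str, list[str]] | None = None,
) -> list[Enzyme]:
    """Build the enzyme list (all seven by default, or a named subset)."""
    spec = dict(DEFAULT_SPECIFICITY if specificity is None else specificity)
    if names is None:
        names = list(spec) + [ALKALINE_PHOSPHATASE]
    enzymes = []
    for name in names:
        if name == ALKALINE_PHOSPHATASE:
            enzymes.append(Enzyme(name=name, modifier=True))
            continue
        if name not in spec:
            raise KeyError(f"no specificity known for enzyme {name!r}")
        if name == "thrombin" and spec[name] == DEFAULT_SPECIFICITY["thrombin"]:
            rules: tuple[CleavageRule, ...] = (_thrombin_rule(),)
        else:
            rules = tuple(CleavageRule.from_string(r) for r in spec[name])
        enzymes.append(Enzyme(name=name, rules=rules))
    return enzymes


def make_peptides(overrides: Mapping[str, str] | None = None) -> list[Peptide]:
    """The seven input peptides, with role tags attached."""
    seqs = dict(_PEPTIDE_SEQUENCES)
    if overrides:
        seqs.update(overrides)
    peptides = []
    for label, seq in seqs.items():
        tags: list[str] = []
        if seq in SLOW_SUBSTRATE_PAIRS:
            tags.append(f"slow_substrate:{SLOW_SUBSTRATE_PAIRS[seq]}")
        if "(pS)" in seq or "pS" in seq:
            tags.append("proinhibitor")
        peptides.append(Peptide(sequence=seq, label=label, role_tags=tuple(tags)))
    return peptides


def load_specificity_config(path) -> dict[str, list[str]]:
    """Read a YAML specificity table {enzyme: [rule strings]}."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"specificity config {path} must map enzymes to rule lists")
    out: dict[str, list[str]] = {}
    for name, rules in data.items():
        if isinstance(rules, str):
            rules = [rules]
        for r in rules:
            CleavageRule.from_string(r)  # validate early
        out[name] = list(rules)
    return out


def save_specificity_config(spec: Mapping[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(spec), fh, sort_keys=True)
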