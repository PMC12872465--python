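"""Recursive cleavage reaction networks.

A small set of proteases is applied recursively to a pool of peptides:
every cleavage product is itself a potential substrate, so the network of
species (peptide fragments) and reactions (cleavage events) is generated
by breadth-first closure up to a configurable fragmentation depth.  An
alkaline-phosphatase "modifier" enzyme adds dephosphorylation reactions
for phosphoserine-containing species without fragmenting them.

Cleavage sites are 1-based residue positions; a cut at site ``i`` severs
the bond after residue ``i`` (standard protease nomenclature), so valid
sites run from 1 to ``len - 1``.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .peptides import (
    PHOSPHOSERINE,
    Peptide,
    format_sequence,
    parse_sequence,
)


@dataclass(frozen=True)
class CleavageRule:
    """One specificity rule of a protease.

    ``kind == "after"``: cut C-terminal of any residue in ``residues``,
    unless the next residue is in ``except_before``.
    ``kind == "before"``: cut N-terminal of any residue in ``residues``.
    """

    kind: str
    residues: frozenset
    except_before: frozenset = frozenset()

    def __post_init__(self):
        if self.kind not in ("after", "before"):
            raise ValueError(f"rule kind must be 'after' or 'before', got {self.kind!r}")
        if not self.residues:
            raise ValueError("rule needs at least one residue")

    def sites(self, tokens: tuple[str, ...]) -> list[int]:
        found = []
        for i in range(1, len(tokens)):  # cut after residue i (1-based)
            if self.kind == "after":
                if tokens[i - 1] in self.residues and tokens[i] not in self.except_before:
                    found.append(i)
            else:  # before
                if tokens[i] in self.residues:
                    found.append(i)
        return found

    @classmethod
    def from_string(cls, text: str) -> "CleavageRule":
        """Parse ``"after:KR except_before:P"`` or ``"before:ILVFMA"``."""
        parts = text.split()
        head = parts[0]
        kind, _, residues = head.partition(":")
        except_before: frozenset = frozenset()
        for extra in parts[1:]:
            key, _, val = extra.partition(":")
            if key != "except_before":
                raise ValueError(f"unknown rule qualifier {key!r} in {text!r}")
            except_before = frozenset(val)
        return cls(kind=kind, residues=frozenset(residues), except_before=except_before)

    def to_string(self) -> str:
        s = f"{self.kind}:{''.join(sorted(self.residues))}"
        if self.except_before:
            s += f" except_before:{''.join(sorted(self.except_before))}"
        return s


@dataclass(frozen=True)
class Enzyme:
    """A catalyst: either a protease (with cleavage rules) or a modifier.

    The only modifier supported is alkaline-phosphatase-style
    dephosphorylation (``modifier=True``), which converts phosphoserine to
    serine.  ``kinetic_scale`` multiplies sampled catalytic rates.
    """

    name: str
    rules: tuple[CleavageRule, ...] = ()
    kinetic_scale: float = 1.0
    modifier: bool = False

    def __post_init__(self):
        if not self.modifier and not self.rules:
            raise ValueError(f"protease {self.name!r} needs a non-empty specificity")


def enumerate_cleavage_sites(peptide: Peptide | str, enzyme: Enzyme) -> list[int]:
    """Ascending, duplicate-free cut positions of ``enzyme`` on ``peptide``.

    The terminal position (= sequence length) is never returned: cutting
    after the last residue produces no fragmentation.
    """
    seq = peptide.sequence if isinstance(peptide, Peptide) else peptide
    tokens = parse_sequence(seq)
    if enzyme.modifier:
        return []
    sites: set[int] = set()
    for rule in enzyme.rules:
        sites.update(rule.sites(tokens))
    return sorted(sites)


@dataclass(frozen=True)
class CleavageEvent:
    """parent --enzyme--> product_n + product_c, cut after residue ``site``."""

    parent: str
    enzyme: str
    site: int
    products: tuple[str, str]


@dataclass(frozen=True)
class Modification:
    """Dephosphorylation: parent --enzyme--> product (no fragmentation)."""

    parent: str
    enzyme: str
    product: str


@dataclass
class ReactionNetwork:
    """Species (fragment sequences) plus the reactions connecting them."""

    species: list[str] = field(default_factory=list)
    cleavages: list[CleavageEvent] = field(default_factory=list)
    modifications: list[Modification] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)  # species -> generation depth

    @property
    def reactions(self) -> list:
        return list(self.cleavages) + list(self.modifications)

    @property
    def n_species(self) -> int:
        return len(self.species)

    def species_index(self) -> dict:
        return {s: i for i, s in enumerate(self.species)}

    def fragments(self, inputs: Iterable[str]) -> list[str]:
        """Species that are not among the given input sequences."""
        inset = set(inputs)
        return [s for s in self.species if s not in inset]


def _cleave(tokens: tuple[str, ...], site: int) -> tuple[str, str]:
    return format_sequence(tokens[:site]), format_sequence(tokens[site:])


def _dephospho(tokens: tuple[str, ...]) -> str:
    return format_sequence(tuple("S" if t == PHOSPHOSERINE else t for t in tokens))


def generate_fragment_network(
    peptides: Sequence[Peptide | str],
    enzymes: Sequence[Enzyme],
    max_depth: int = 6,
) -> ReactionNetwork:
    """Breadth-first closure of the cleavage network.

    Every fragment reachable by at most ``max_depth`` successive cleavages
    is included.  Dephosphorylation (when a modifier enzyme is present)
    does not consume fragmentation depth: the product inherits the
    parent's depth.
    """
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    proteases = [e for e in enzymes if not e.modifier]
    modifiers = [e for e in enzymes if e.modifier]
    names = [e.name for e in enzymes]
    if len(set(names)) != len(names):
        raise ValueError("enzyme names must be unique")

    net = ReactionNetwork()
    depth: dict[str, int] = {}
    queue: deque[str] = deque()
    for p in peptides:
        seq = p.sequence if isinstance(p, Peptide) else p
        parse_sequence(seq)
        if seq not in depth:
            depth[seq] = 0
            net.species.append(seq)
            queue.append(seq)

    seen_cleavages: set[tuple] = set()
    seen_mods: set[tuple] = set()
    while queue:
        seq = queue.popleft()
        d = depth[seq]
        tokens = parse_sequence(seq)
        # dephosphorylation keeps the species at the same depth
        if modifiers and PHOSPHOSERINE in tokens:
            product = _dephospho(tokens)
            for mod in modifiers:
                key = (seq, mod.name)
                if key not in seen_mods:
                    seen_mods.add(key)
                    net.modifications.append(Modification(seq, mod.name, product))
            if product not in depth:
                depth[product] = d
                net.species.append(product)
                queue.append(product)
        if d >= max_depth:
            continue
        for enz in proteases:
            for site in enumerate_cleavage_sites(seq, enz):
                prod_n, prod_c = _cleave(tokens, site)
                key = (seq, enz.name, site)
                if key not in seen_cleavages:
                    seen_cleavages.add(key)
                    net.cleavages.append(CleavageEvent(seq, enz.name, site, (prod_n, prod_c)))
                for prod in (prod_n, prod_c):
                    if prod not in depth:
                        depth[prod] = d + 1
                        net.species.append(prod)
                        queue.append(prod)
    net.provenance = depth
    return net


# ---------------------------------------------------------------------------
# plain-text round-trip export

def export_network(net: ReactionNetwork) -> str:
    """Serialize as a species table plus one reaction per line."""
    lines = ["# species\tid\tsequence\tdepth"]
    for i, s in enumerate(net.species):
        lines.append(f"S\t{i}\t{s}\t{net.provenance.get(s, 0)}")
    lines.append("# reactions\tkind\tparent\tenzyme\tsite\tproduct1\tproduct2")
    for c in net.cleavages:
        lines.append(f"C\t{c.parent}\t{c.enzyme}\t{c.site}\t{c.products[0]}\t{c.products[1]}")
    for m in net.modifications:
        lines.append(f"M\t{m.parent}\t{m.enzyme}\t-\t{m.product}\t-")
    return "\n".join(lines) + "\n"


def import_network(text: str) -> ReactionNetwork:
    net = ReactionNetwork()
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if parts[0] == "S":
            _, _idx, seq, d = parts
            net.species.append(seq)
            net.provenance[seq] = int(d)
        elif parts[0] == "C":
            _, parent, enzyme, site, p1, p2 = parts
            net.cleavages.append(CleavageEvent(parent, enzyme, int(site), (p1, p2)))
        elif parts[0] == "M":
            _, parent, enzyme, _site, product, _ = parts
            net.modifications.append(Modification(parent, enzyme, product))
        else:
            raise ValueError(f"unrecognized record {parts[0]!r}")
    return net
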