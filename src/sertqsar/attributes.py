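"""CORAL-style attribute inventories from SMILES strings.

A molecule is decomposed into three attribute tiers:

* local SMILES attributes -- single SMILES atoms (``Sk``) and sliding
  windows of two (``SSk``) and three (``SSSk``) adjacent SMILES atoms,
  read off the SMILES character stream as written;
* global SMILES attributes -- whole-molecule presence codes (``NOSP``,
  ``HALO``, ``BOND``, ``ATOMPAIR``, ``MAXCOUNT``, ``HARD``);
* hydrogen-suppressed-graph invariants -- per heavy atom: degree
  (``EC0``), simple-path counts of length two/three (``PT2``/``PT3``),
  valence-shell degree sums at distance two/three (``VS2``/``VS3``) and
  carbon/heteroatom nearest-neighbour counts (``NNC``).

Every attribute is rendered as a fixed-layout code string (12 characters
for the SMILES tiers, matching the published printing convention) so the
inventory of a molecule is a plain multiset of strings.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
from rdkit import Chem

__all__ = [
    "AttributeInventory",
    "tokenize_smiles",
    "local_attributes",
    "global_attributes",
    "graph_invariants",
    "extract_inventory",
    "SmilesParseError",
]

CODE_WIDTH = 12
_FIELD = 4  # per-token field width inside SSk/SSSk codes

# Elements eligible for ATOMPAIR codes, in canonical order.
ATOMPAIR_ELEMENTS = ("F", "N", "O", "S", "P", "Cl", "Br", "I")

# HARD presence-bit layout: 11 flags behind the "$" sigil.  The order is a
# package constant chosen to reproduce the published exemplar code
# "$00011001000" (molecule containing N, O and F only).
HARD_LAYOUT = ("S", "P", "=", "N", "O", "#", "Cl", "F", "Br", "I", "@")

_TWO_CHAR = ("Cl", "Br")
_BOND_CHARS = frozenset("=#/\\")


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be tokenized or parsed."""


@dataclass
class AttributeInventory:
    """Multiset of attribute codes for one molecule."""

    molecule_id: str
    counts: Counter = field(default_factory=Counter)

    def total(self) -> int:
        return sum(self.counts.values())

    def __contains__(self, code: str) -> bool:
        return self.counts[code] > 0


def tokenize_smiles(smiles: str) -> list[str]:
    """Split a SMILES string into SMILES atoms (``Sk`` tokens).

    Two-character element symbols (Cl, Br), bracket atoms, %-prefixed
    ring closures and every other single character are each one token.
    Closing parentheses are normalized to ``(`` so that branching is a
    single attribute, as in the published attribute listings.
    """
    if not smiles:
        raise SmilesParseError("empty SMILES string")
    tokens: list[str] = []
    depth = 0
    i = 0
    n = len(smiles)
    while i < n:
        ch = smiles[i]
        if ch == "[":
            j = smiles.find("]", i)
            if j < 0:
                raise SmilesParseError(f"unclosed bracket atom at position {i}")
            tokens.append(smiles[i : j + 1])
            i = j + 1
            continue
        if ch == "]":
            raise SmilesParseError(f"unmatched ']' at position {i}")
        if ch == "%":
            m = re.match(r"%\d{2}", smiles[i:])
            if not m:
                raise SmilesParseError(f"malformed ring closure at position {i}")
            tokens.append(m.group())
            i += len(m.group())
            continue
        if smiles[i : i + 2] in _TWO_CHAR:
            tokens.append(smiles[i : i + 2])
            i += 2
            continue
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise SmilesParseError(f"unmatched ')' at position {i}")
            ch = "("  # open/close branching collapse to one token
        tokens.append(ch)
        i += 1
    if depth != 0:
        raise SmilesParseError("unbalanced parentheses")
    return tokens


def _pad(code: str) -> str:
    return code.ljust(CODE_WIDTH, ".")


def _window_code(window: tuple[str, ...]) -> str:
    """Canonical fixed-width code for a 2- or 3-token sliding window.

    The two directional readings are rendered and the lexicographically
    larger one is kept, which reproduces the published code orientation
    (e.g. the pair C,n prints as ``n...C.......``).
    """
    fwd = "".join(t.ljust(_FIELD, ".") for t in window)
    rev = "".join(t.ljust(_FIELD, ".") for t in reversed(window))
    return _pad(max(fwd, rev))


def local_attributes(tokens: list[str]) -> Counter:
    """Sk/SSk/SSSk codes from an ordered token stream."""
    counts: Counter = Counter()
    for t in tokens:
        counts[_pad(t)] += 1
    for i in range(len(tokens) - 1):
        counts[_window_code(tuple(tokens[i : i + 2]))] += 1
    for i in range(len(tokens) - 2):
        counts[_window_code(tuple(tokens[i : i + 3]))] += 1
    return counts


def _element_presence(tokens: list[str]) -> set[str]:
    """Element symbols present, aromatic forms mapped to the element."""
    present: set[str] = set()
    for t in tokens:
        if t.startswith("["):
            m = re.search(r"([A-Z][a-z]?|[cnosp])", t)
            if m:
                sym = m.group()
                present.add(sym if sym[0].isupper() else sym.upper())
        elif t in _TWO_CHAR or (len(t) == 1 and t.isalpha()):
            present.add(t if t[0].isupper() else t.upper())
    return present


def global_attributes(smiles: str) -> Counter:
    """Whole-molecule presence codes: NOSP, HALO, BOND, ATOMPAIR, MAXCOUNT, HARD."""
    tokens = tokenize_smiles(smiles)
    present = _element_presence(tokens)
    counts: Counter = Counter()

    nosp = "".join("1" if e in present else "0" for e in ("N", "O", "S", "P"))
    counts[_pad(f"NOSP{nosp}0000")[:CODE_WIDTH]] += 1
    halo = "".join("1" if e in present else "0" for e in ("F", "Cl", "Br", "I"))
    counts[f"HALO{halo}0000"] += 1
    bond = "".join(
        "1" if flag else "0"
        for flag in (
            "=" in smiles,
            "#" in smiles,
            ("/" in smiles or "\\" in smiles),
            False,
        )
    )
    counts[f"BOND{bond}0000"] += 1

    pair_pool = [e for e in ATOMPAIR_ELEMENTS if e in present]
    for i, e1 in enumerate(pair_pool):
        for e2 in pair_pool[i + 1 :]:
            left = f"++++{e1}"
            mid = "-" * (CODE_WIDTH - 3 - len(left) - len(e2))
            counts[f"{left}{mid}{e2}==="] += 1

    # MAXCOUNT: longest run of consecutive identical uppercase C/N/O/S tokens.
    for el in ("C", "N", "O", "S"):
        best = run = 0
        for t in tokens:
            run = run + 1 if t == el else 0
            best = max(best, run)
        counts[_pad(f"{el}max.{best}")] += 1

    hard_present = present | ({"="} if "=" in smiles else set()) \
        | ({"#"} if "#" in smiles else set()) \
        | ({"@"} if "@" in smiles else set())
    bits = "".join("1" if f in hard_present else "0" for f in HARD_LAYOUT)
    counts[f"${bits}"] += 1
    return counts


def _mol_graph(smiles: str) -> nx.Graph:
    mol = Chem.MolFromSmiles(smiles, sanitize=True)
    if mol is None:
        raise SmilesParseError(f"RDKit cannot parse SMILES: {smiles!r}")
    g = nx.Graph()
    for atom in mol.GetAtoms():
        g.add_node(atom.GetIdx(), element=atom.GetSymbol())
    for bond in mol.GetBonds():
        g.add_edge(bond.GetBeginAtomIdx(), bond.GetEndAtomIdx())
    return g


def _count_simple_paths(g: nx.Graph, start: int, length: int) -> int:
    """Number of simple paths with `length` edges starting at `start`."""
    count = 0
    stack = [(start, {start})]
    for _ in range(length):
        nxt = []
        for node, seen in stack:
            for nb in g[node]:
                if nb not in seen:
                    nxt.append((nb, seen | {nb}))
        stack = nxt
    return len(stack)


def node_invariants(g: nx.Graph, node) -> dict[str, int]:
    """Topological invariants for one vertex of a hydrogen-suppressed graph."""
    deg = g.degree[node]
    sp = nx.single_source_shortest_path_length(g, node)
    shell2 = [m for m, d in sp.items() if d == 2]
    shell3 = [m for m, d in sp.items() if d == 3]
    return {
        "EC0": deg,
        "PT2": _count_simple_paths(g, node, 2),
        "PT3": _count_simple_paths(g, node, 3),
        "VS2": sum(g.degree[m] for m in shell2),
        "VS3": sum(g.degree[m] for m in shell3),
    }


def graph_invariants(smiles: str) -> Counter:
    """Per-heavy-atom topological invariant codes on the H-suppressed graph."""
    g = _mol_graph(smiles)
    counts: Counter = Counter()
    for node, data in g.nodes(data=True):
        el = data["element"]
        deg = g.degree[node]
        for fam, v in node_invariants(g, node).items():
            counts[_pad(f"{fam}.{el}.{v}")] += 1
        n_carbon = sum(1 for nb in g[node] if g.nodes[nb]["element"] == "C")
        counts[_pad(f"NNC.{el}.{n_carbon}{deg - n_carbon}")] += 1
    return counts


def extract_inventory(
    smiles: str,
    molecule_id: str = "",
    include_graph: bool = True,
) -> AttributeInventory:
    """Full attribute inventory (local + global [+ graph]) for one SMILES."""
    counts = local_attributes(tokenize_smiles(smiles))
    counts += global_attributes(smiles)
    if include_graph:
        counts += graph_invariants(smiles)
    return AttributeInventory(molecule_id=molecule_id, counts=counts)
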