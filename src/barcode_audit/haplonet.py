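"""Haplotype collapse and statistical-parsimony networks.

Sequences (typically one to three closely related species) are first
collapsed into haplotypes by exact string identity over the five-state
alphabet {A, C, G, T, -}: an alignment gap is a character state, so two
sequences differing only by an indel are distinct haplotypes. Sequences
containing N are attached to an existing haplotype only when exactly one
haplotype is compatible at all their unambiguous sites; otherwise they
are held out (reported, never silently dropped).

The network connects haplotypes in ascending order of mutational steps
(five-state Hamming distance), honouring a user-specified maximum
number of connection steps (default 25); pairs further apart than the
cap remain in separate components. When several connections tie at the
merging step count, all tied edges are kept — the result is a network
with reticulations, not a tree. Multi-step connections are decomposed
into single-step edges through inferred unsampled intermediates, so
every drawn line represents exactly one mutational change.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .library import BarcodeLibrary

DEFAULT_MAX_STEPS = 25


@dataclass(frozen=True)
class Haplotype:
    """A unique five-state sequence and the specimens carrying it."""

    haplotype_id: str  # h1, h2, ... by descending frequency
    sequence: str
    members: tuple[str, ...]
    species_spectrum: dict[str, int]

    @property
    def frequency(self) -> int:
        return len(self.members)

    @property
    def shared(self) -> bool:
        return len(self.species_spectrum) >= 2


def _compatible(amb: str, full: str) -> bool:
    """True if `amb` (may contain N) matches `full` at all non-N sites."""
    return all(a == b or a == "N" for a, b in zip(amb, full))


def collapse_haplotypes(
    library: BarcodeLibrary,
) -> tuple[list[Haplotype], list[str]]:
    """Collapse an aligned library subset into haplotypes.

    Returns (haplotypes, held_out_specimen_ids). Naming is deterministic:
    h1 is the most frequent haplotype, ties broken by the smallest member
    specimen ID.
    """
    library.require_aligned("haplotype collapse")
    clean: dict[str, list] = {}
    ambiguous = []
    for rec in library:
        if "N" in rec.sequence:
            ambiguous.append(rec)
        else:
            clean.setdefault(rec.sequence, []).append(rec)
    held_out: list[str] = []
    for rec in ambiguous:
        compatible = [s for s in clean if _compatible(rec.sequence, s)]
        if len(compatible) == 1:
            clean[compatible[0]].append(rec)
        else:
            held_out.append(rec.specimen_id)

    groups = sorted(
        clean.items(),
        key=lambda kv: (-len(kv[1]), min(r.specimen_id for r in kv[1])),
    )
    haplotypes = []
    for rank, (seq, recs) in enumerate(groups, start=1):
        spectrum: dict[str, int] = {}
        for r in recs:
            spectrum[r.species] = spectrum.get(r.species, 0) + 1
        haplotypes.append(
            Haplotype(
                haplotype_id=f"h{rank}",
                sequence=seq,
                members=tuple(sorted(r.specimen_id for r in recs)),
                species_spectrum=spectrum,
            )
        )
    return haplotypes, held_out


def mutation_steps(seq_a: str, seq_b: str) -> int:
    """Five-state Hamming distance (gap counts as a state)."""
    if len(seq_a) != len(seq_b):
        raise ValueError("haplotypes must be aligned (equal length)")
    return sum(1 for a, b in zip(seq_a, seq_b) if a != b)


def shared_haplotypes(haplotypes: list[Haplotype]) -> list[Haplotype]:
    """Haplotypes carried by two or more species."""
    return [h for h in haplotypes if h.shared]


@dataclass
class HaplotypeNetwork:
    """Single-step mutation graph over observed + inferred haplotypes.

    Node attributes: ``kind`` ("observed"/"inferred"), ``frequency``,
    ``species_spectrum`` (observed only), ``sequence``.
    """

    graph: nx.Graph
    max_steps: int

    @property
    def observed_nodes(self) -> list[str]:
        return [n for n, a in self.graph.nodes(data=True) if a["kind"] == "observed"]

    @property
    def inferred_nodes(self) -> list[str]:
        return [n for n, a in self.graph.nodes(data=True) if a["kind"] == "inferred"]

    @property
    def components(self) -> list[set[str]]:
        return [set(c) for c in nx.connected_components(self.graph)]

    def n_components_observed(self) -> int:
        """Number of components, counting only those holding observed nodes."""
        return sum(
            1
            for c in nx.connected_components(self.graph)
            if any(self.graph.nodes[n]["kind"] == "observed" for n in c)
        )

    def edges_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"node_a": a, "node_b": b} for a, b in sorted(self.graph.edges())]
        )

    def nodes_frame(self) -> pd.DataFrame:
        rows = []
        for n, a in sorted(self.graph.nodes(data=True)):
            rows.append(
                {
                    "node": n,
                    "kind": a["kind"],
                    "frequency": a.get("frequency", 0),
                    "species": ";".join(
                        f"{sp}:{c}" for sp, c in sorted(a.get("species_spectrum", {}).items())
                    ),
                }
            )
        return pd.DataFrame(rows)


def _intermediate_path(seq_a: str, seq_b: str) -> list[str]:
    """Intermediate sequences along one deterministic single-step path.

    Differing positions are mutated in ascending positional order; the
    resulting chain has Hamming-1 consecutive members.
    """
    diffs = [i for i, (a, b) in enumerate(zip(seq_a, seq_b)) if a != b]
    out = []
    cur = list(seq_a)
    for pos in diffs[:-1]:
        cur[pos] = seq_b[pos]
        out.append("".join(cur))
    return out


def parsimony_network(
    haplotypes: list[Haplotype], max_steps: int = DEFAULT_MAX_STEPS
) -> HaplotypeNetwork:
    """Build the connection-limited single-step network.

    Candidate haplotype pairs are processed level by level in ascending
    step count; within a level, every pair joining two still-separate
    components is connected (component membership frozen at the start of
    the level, so equally parsimonious alternative connections are all
    retained). Pairs needing more than ``max_steps`` changes are never
    connected directly.
    """
    if not haplotypes:
        raise ValueError("no haplotypes to connect")
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    g = nx.Graph()
    for h in haplotypes:
        g.add_node(
            h.haplotype_id,
            kind="observed",
            frequency=h.frequency,
            species_spectrum=dict(h.species_spectrum),
            sequence=h.sequence,
        )
    by_id = {h.haplotype_id: h for h in haplotypes}

    pairs = []
    for ha, hb in itertools.combinations(haplotypes, 2):
        k = mutation_steps(ha.sequence, hb.sequence)
        pairs.append((k, -(ha.frequency + hb.frequency), ha.haplotype_id, hb.haplotype_id))
    pairs.sort()

    # union-find over observed haplotypes
    parent = {h.haplotype_id: h.haplotype_id for h in haplotypes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    accepted: list[tuple[str, str, int]] = []
    i = 0
    n_inferred = 0
    while i < len(pairs):
        k = pairs[i][0]
        if k > max_steps:
            break
        level = []
        while i < len(pairs) and pairs[i][0] == k:
            level.append(pairs[i])
            i += 1
        # freeze membership at level start so tied alternatives all survive
        comp_at_start = {h.haplotype_id: find(h.haplotype_id) for h in haplotypes}
        merges = []
        for _, _, a, b in level:
            if comp_at_start[a] != comp_at_start[b]:
                accepted.append((a, b, k))
                merges.append((a, b))
        for a, b in merges:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[rb] = ra

    for a, b, k in accepted:
        if k == 1:
            g.add_edge(a, b)
            continue
        chain = [a]
        for step_seq in _intermediate_path(by_id[a].sequence, by_id[b].sequence):
            n_inferred += 1
            node = f"i{n_inferred}"
            g.add_node(node, kind="inferred", frequency=0, sequence=step_seq)
            chain.append(node)
        chain.append(b)
        for u, v in zip(chain, chain[1:]):
            g.add_edge(u, v)

    return HaplotypeNetwork(graph=g, max_steps=max_steps)


def haplotype_membership_frame(
    haplotypes: list[Haplotype], held_out: list[str] | None = None
) -> pd.DataFrame:
    rows = []
    for h in haplotypes:
        for m in h.members:
            rows.append({"specimen_id": m, "haplotype": h.haplotype_id})
    for m in held_out or []:
        rows.append({"specimen_id": m, "haplotype": ""})
    return pd.DataFrame(rows)


def write_graphml(network: HaplotypeNetwork, sink: str) -> None:
    g = nx.Graph()
    for n, a in network.graph.nodes(data=True):
        g.add_node(
            n,
            kind=a["kind"],
            frequency=int(a.get("frequency", 0)),
            species=";".join(
                f"{sp}:{c}" for sp, c in sorted(a.get("species_spectrum", {}).items())
            ),
        )
    g.add_edges_from(network.graph.edges())
    nx.write_graphml(g, sink)
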