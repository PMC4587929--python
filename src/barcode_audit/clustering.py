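"""Threshold OTU clustering and species/OTU concordance.

OTUs are the connected components of the graph whose edges join
specimens at K2P distance strictly below a threshold (single-linkage
closure). This is an explicit, reproducible proxy for index-number style
barcode clusters: it reproduces the phenomenology of interest — one
species split over several OTUs (deep intraspecific divergence) and one
OTU shared by several species (haplotype sharing) — with a transparent
rule. Undefined distances are treated as "not below threshold".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .distance import DistanceMatrix
from .library import BarcodeLibrary


@dataclass(frozen=True)
class OTUPartition:
    """Total assignment of specimens to OTUs at one threshold.

    OTU labels are deterministic: the lexicographically smallest member
    specimen ID, so partitions are comparable across runs.
    """

    threshold: float  # percent
    assignment: dict[str, str]  # specimen_id -> OTU label
    n_undefined_pairs: int = 0

    @property
    def labels(self) -> list[str]:
        return sorted(set(self.assignment.values()))

    @property
    def n_otus(self) -> int:
        return len(set(self.assignment.values()))

    def members(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for sid, otu in self.assignment.items():
            out.setdefault(otu, []).append(sid)
        return {k: sorted(v) for k, v in out.items()}


def threshold_clusters(dm: DistanceMatrix, threshold: float) -> OTUPartition:
    """Single-linkage OTUs: components of the d < threshold graph.

    ``threshold`` is in percent; comparison on the stored proportions is
    strict (<), so two specimens exactly at the threshold stay apart.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0 (percent)")
    t = threshold / 100.0
    with np.errstate(invalid="ignore"):
        adj = dm.d < t  # NaN compares False: undefined treated as >= t
    iu, ju = np.triu_indices(len(dm), 1)
    n_undef = int(np.isnan(dm.d[iu, ju]).sum())
    graph = csr_matrix(adj)
    n_comp, labels = connected_components(graph, directed=False)
    comp_label: dict[int, str] = {}
    for comp in range(n_comp):
        members = [dm.ids[i] for i in np.where(labels == comp)[0]]
        comp_label[comp] = min(members)
    assignment = {dm.ids[i]: comp_label[labels[i]] for i in range(len(dm))}
    return OTUPartition(threshold=threshold, assignment=assignment, n_undefined_pairs=n_undef)


@dataclass(frozen=True)
class ConcordanceReport:
    """Species <-> OTU concordance counts (abstract-style tally)."""

    species_otu_counts: dict[str, int]  # species -> number of OTUs it spans
    otus_shared_by_multiple_species: dict[str, list[str]]  # OTU -> species list
    per_species_otus: dict[str, list[str]]

    @property
    def n_species(self) -> int:
        return len(self.species_otu_counts)

    def n_species_with_otus(self, k: int) -> int:
        return sum(1 for v in self.species_otu_counts.values() if v == k)

    @property
    def n_species_1otu(self) -> int:
        return self.n_species_with_otus(1)

    @property
    def n_species_2otu(self) -> int:
        return self.n_species_with_otus(2)

    @property
    def n_species_3otu(self) -> int:
        return self.n_species_with_otus(3)

    @property
    def n_species_more(self) -> int:
        return sum(1 for v in self.species_otu_counts.values() if v > 3)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species": list(self.species_otu_counts),
                "n_otus": list(self.species_otu_counts.values()),
                "otus": [";".join(self.per_species_otus[s]) for s in self.species_otu_counts],
            }
        )


def concordance(partition: OTUPartition, library: BarcodeLibrary) -> ConcordanceReport:
    """Count OTUs per species and species per OTU."""
    sp_of = dict(zip(library.ids, library.species_labels))
    missing = [s for s in partition.assignment if s not in sp_of]
    if missing:
        raise ValueError(f"partition contains specimens absent from library: {missing[:5]}")
    per_species: dict[str, set[str]] = {}
    per_otu: dict[str, set[str]] = {}
    for sid, otu in partition.assignment.items():
        sp = sp_of[sid]
        per_species.setdefault(sp, set()).add(otu)
        per_otu.setdefault(otu, set()).add(sp)
    # preserve library species order
    ordered_species = list(dict.fromkeys(library.species_labels))
    return ConcordanceReport(
        species_otu_counts={sp: len(per_species[sp]) for sp in ordered_species},
        otus_shared_by_multiple_species={
            otu: sorted(sps) for otu, sps in sorted(per_otu.items()) if len(sps) > 1
        },
        per_species_otus={sp: sorted(per_species[sp]) for sp in ordered_species},
    )


def assignments_to_frame(partition: OTUPartition, library: BarcodeLibrary) -> pd.DataFrame:
    sp_of = dict(zip(library.ids, library.species_labels))
    return pd.DataFrame(
        {
            "specimen_id": list(partition.assignment),
            "species": [sp_of.get(s, "") for s in partition.assignment],
            "otu": list(partition.assignment.values()),
        }
    )
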