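"""Leave-one-out identification simulation (Best Match, Best Close
Match, All Species Barcodes).

Every sequence is used once as a query against the rest of the library,
and the molecular identification is compared with the prior (metadata)
species label:

* **BM** — the nearest neighbour identifies the query regardless of
  distance. Never yields "no ID"; a species represented by a single
  sequence (singleton) is therefore always identified incorrectly.
* **BCM** — like BM but only matches strictly below a distance
  threshold count; no match below threshold gives "no ID", and a
  nearest-distance tie spanning several species gives "ambiguous".
* **ASB** — emulates unanimity-style engines: the query is identified
  only when *all* sequences below the threshold agree; a mixture of
  species below the threshold is "ambiguous".

Singleton handling follows the common simulation design: when singletons
are excluded they are removed from the *query* set only, remaining in
the reference, so they can still attract (incorrect) matches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .distance import DistanceMatrix

CRITERIA = ("BM", "BCM", "ASB")
OUTCOMES = ("correct", "incorrect", "ambiguous", "no_id")


@dataclass(frozen=True)
class IdentificationOutcome:
    query_id: str
    criterion: str
    threshold: float | None  # percent; None for BM
    outcome: str
    matched_species: tuple[str, ...]
    min_distance: float  # percent; NaN if no defined distance

    def as_dict(self) -> dict:
        return {
            "query_id": self.query_id,
            "criterion": self.criterion,
            "threshold_pct": self.threshold,
            "outcome": self.outcome,
            "matched_species": ";".join(self.matched_species),
            "min_distance_pct": self.min_distance,
        }


def _reference_view(dm: DistanceMatrix, qi: int):
    """(distances, species) for all reference rows != query, NaN dropped."""
    row = dm.d[qi].copy()
    row[qi] = np.nan
    mask = ~np.isnan(row)
    return row[mask], np.asarray(dm.species)[mask]


def best_match(
    dm: DistanceMatrix, query_id: str, tie_tol: float = 0.0
) -> IdentificationOutcome:
    """Nearest-neighbour identification, no distance cut-off.

    A tie at the minimum distance resolves to "correct" if any tied
    match is conspecific (liberal tie policy — the criterion has no
    ambiguous category).
    """
    qi = dm.index_of(query_id)
    dist, sp = _reference_view(dm, qi)
    if dist.size == 0:
        raise ValueError(f"query {query_id!r} has no defined reference distance")
    m = dist.min()
    tied = sp[dist <= m + tie_tol]
    true_sp = dm.species[qi]
    outcome = "correct" if true_sp in tied else "incorrect"
    return IdentificationOutcome(
        query_id=query_id,
        criterion="BM",
        threshold=None,
        outcome=outcome,
        matched_species=tuple(sorted(set(tied))),
        min_distance=float(m) * 100,
    )


def best_close_match(
    dm: DistanceMatrix, query_id: str, threshold: float, tie_tol: float = 0.0
) -> IdentificationOutcome:
    """Nearest neighbour below a threshold (percent, strict <)."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0 (percent)")
    t = threshold / 100.0
    qi = dm.index_of(query_id)
    dist, sp = _reference_view(dm, qi)
    below = dist < t
    true_sp = dm.species[qi]
    if not below.any():
        outcome, matched = "no_id", ()
        min_d = float(dist.min()) * 100 if dist.size else float("nan")
    else:
        m = dist[below].min()
        tied = sp[below & (dist <= m + tie_tol)]
        uniq = sorted(set(tied))
        min_d = float(m) * 100
        if len(uniq) > 1:
            outcome, matched = "ambiguous", tuple(uniq)
        else:
            outcome = "correct" if uniq[0] == true_sp else "incorrect"
            matched = tuple(uniq)
    return IdentificationOutcome(
        query_id=query_id,
        criterion="BCM",
        threshold=threshold,
        outcome=outcome,
        matched_species=matched,
        min_distance=min_d,
    )


def all_species_barcodes(
    dm: DistanceMatrix, query_id: str, threshold: float
) -> IdentificationOutcome:
    """Unanimity criterion: every match below threshold must be conspecific."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0 (percent)")
    t = threshold / 100.0
    qi = dm.index_of(query_id)
    dist, sp = _reference_view(dm, qi)
    below = dist < t
    true_sp = dm.species[qi]
    if not below.any():
        outcome, matched = "no_id", ()
        min_d = float(dist.min()) * 100 if dist.size else float("nan")
    else:
        uniq = sorted(set(sp[below]))
        matched = tuple(uniq)
        min_d = float(dist[below].min()) * 100
        if len(uniq) > 1:
            outcome = "ambiguous"
        elif uniq[0] == true_sp:
            outcome = "correct"
        else:
            outcome = "incorrect"
    return IdentificationOutcome(
        query_id=query_id,
        criterion="ASB",
        threshold=threshold,
        outcome=outcome,
        matched_species=matched,
        min_distance=min_d,
    )


@dataclass(frozen=True)
class IdentificationTally:
    """Outcome counts for one criterion x threshold configuration."""

    criterion: str
    threshold: float | None  # percent
    counts: dict[str, int]
    exclude_singletons: bool
    n_queries: int

    def __post_init__(self) -> None:
        assert sum(self.counts.values()) == self.n_queries

    def as_dict(self) -> dict:
        label = self.criterion if self.threshold is None else f"{self.criterion} {self.threshold:g}%"
        return {"configuration": label, "exclude_singletons": self.exclude_singletons,
                "n_queries": self.n_queries, **self.counts}


def run_simulation(
    dm: DistanceMatrix,
    criteria: Iterable[str] = CRITERIA,
    thresholds: Iterable[float] = (1.0,),
    exclude_singletons: bool = False,
    tie_tol: float = 0.0,
) -> tuple[list[IdentificationTally], list[IdentificationOutcome]]:
    """Leave-one-out simulation over every retained query.

    Returns (tallies, per-query outcomes). ``thresholds`` apply to BCM
    and ASB only. With ``exclude_singletons`` the queries whose species
    has a single sequence are skipped; the reference always contains the
    full library minus the query itself.
    """
    species = np.asarray(dm.species)
    if species.size == 0:
        raise ValueError("distance matrix carries no species labels")
    counts_per_species = pd.Series(species).value_counts()
    singleton_species = set(counts_per_species[counts_per_species == 1].index)

    queries = [
        i for i in range(len(dm))
        if not (exclude_singletons and species[i] in singleton_species)
    ]
    if not queries:
        raise ValueError("no queries left after singleton exclusion")

    outcomes: list[IdentificationOutcome] = []
    for qi in queries:
        qid = dm.ids[qi]
        for crit in criteria:
            if crit == "BM":
                outcomes.append(best_match(dm, qid, tie_tol=tie_tol))
            elif crit == "BCM":
                for t in thresholds:
                    outcomes.append(best_close_match(dm, qid, t, tie_tol=tie_tol))
            elif crit == "ASB":
                for t in thresholds:
                    outcomes.append(all_species_barcodes(dm, qid, t))
            else:
                raise ValueError(f"unknown criterion {crit!r}")

    tallies = []
    configs = []
    for crit in criteria:
        if crit == "BM":
            configs.append(("BM", None))
        else:
            configs.extend((crit, t) for t in thresholds)
    for crit, t in configs:
        sel = [o for o in outcomes if o.criterion == crit and o.threshold == t]
        counts = {k: 0 for k in OUTCOMES}
        for o in sel:
            counts[o.outcome] += 1
        tallies.append(
            IdentificationTally(
                criterion=crit,
                threshold=t,
                counts=counts,
                exclude_singletons=exclude_singletons,
                n_queries=len(sel),
            )
        )
    return tallies, outcomes


def tallies_to_frame(tallies: list[IdentificationTally]) -> pd.DataFrame:
    return pd.DataFrame([t.as_dict() for t in tallies])


def outcomes_to_frame(outcomes: list[IdentificationOutcome]) -> pd.DataFrame:
    return pd.DataFrame([o.as_dict() for o in outcomes])
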