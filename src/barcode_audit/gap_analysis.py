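"""Barcoding-gap screening: per-species distance summaries.

For every species the intraspecific mean/maximum pairwise K2P distance
and the distance to its nearest-neighbour species are computed. Species
whose maximum intraspecific distance exceeds a screening threshold
(default 2.2%, strictly greater) are flagged as candidates for deep
intraspecific splits; species *pairs* whose minimum interspecific
distance falls below the same threshold point at possible haplotype
sharing or very recent divergence.

All summary fields are expressed in percent; undefined pairs in the
distance matrix are skipped and tallied in a QC report so they cannot
bias maxima.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distance import DistanceMatrix

DEFAULT_SCREENING_THRESHOLD = 2.2  # percent


def _species_blocks(dm: DistanceMatrix) -> dict[str, np.ndarray]:
    if not dm.species:
        raise ValueError("distance matrix carries no species labels")
    blocks: dict[str, list[int]] = {}
    for i, sp in enumerate(dm.species):
        blocks.setdefault(sp, []).append(i)
    return {sp: np.array(idx) for sp, idx in blocks.items()}


@dataclass(frozen=True)
class SpeciesSummary:
    """Per-species intraspecific statistics and nearest-neighbour record."""

    species: str
    n: int
    mean_intra: float  # percent; NaN for singletons
    max_intra: float  # percent; NaN for singletons
    nn_species: str | None
    nn_distance: float  # percent; NaN if no other species
    n_undefined_intra: int
    flagged: bool

    def as_dict(self) -> dict:
        return {
            "species": self.species,
            "n": self.n,
            "mean_intra_pct": self.mean_intra,
            "max_intra_pct": self.max_intra,
            "nn_species": self.nn_species,
            "nn_distance_pct": self.nn_distance,
            "n_undefined_intra": self.n_undefined_intra,
            "flagged": self.flagged,
        }


def species_summaries(
    dm: DistanceMatrix, threshold: float = DEFAULT_SCREENING_THRESHOLD
) -> list[SpeciesSummary]:
    """One summary per species, in order of first appearance.

    ``threshold`` (percent) only sets the ``flagged`` field; it does not
    alter any statistic.
    """
    blocks = _species_blocks(dm)
    multiple_species = len(blocks) >= 2
    out = []
    for sp, idx in blocks.items():
        # intraspecific upper triangle
        if len(idx) >= 2:
            sub = dm.d[np.ix_(idx, idx)]
            iu, ju = np.triu_indices(len(idx), 1)
            vals = sub[iu, ju]
            n_undef = int(np.isnan(vals).sum())
            vals = vals[~np.isnan(vals)]
            mean_intra = float(vals.mean()) * 100 if vals.size else float("nan")
            max_intra = float(vals.max()) * 100 if vals.size else float("nan")
        else:
            n_undef = 0
            mean_intra = max_intra = float("nan")

        nn_species: str | None = None
        nn_distance = float("nan")
        if multiple_species:
            other = np.array([i for i in range(len(dm)) if dm.species[i] != sp])
            inter = dm.d[np.ix_(idx, other)]
            if np.isfinite(inter).any():
                flat = np.nanmin(inter)
                pos = np.argwhere(inter == flat)[0]
                nn_species = dm.species[other[pos[1]]]
                nn_distance = float(flat) * 100

        out.append(
            SpeciesSummary(
                species=sp,
                n=len(idx),
                mean_intra=mean_intra,
                max_intra=max_intra,
                nn_species=nn_species,
                nn_distance=nn_distance,
                n_undefined_intra=n_undef,
                flagged=bool(max_intra > threshold) if np.isfinite(max_intra) else False,
            )
        )
    return out


def flag_species(
    summaries: list[SpeciesSummary], threshold: float = DEFAULT_SCREENING_THRESHOLD
) -> list[SpeciesSummary]:
    """Species with max intraspecific distance strictly above ``threshold`` (%),
    sorted descending by that maximum (ties by name for determinism)."""
    flagged = [
        s for s in summaries if np.isfinite(s.max_intra) and s.max_intra > threshold
    ]
    return sorted(flagged, key=lambda s: (-s.max_intra, s.species))


def low_interspecific_pairs(
    dm: DistanceMatrix, threshold: float = DEFAULT_SCREENING_THRESHOLD
) -> list[tuple[str, str, float]]:
    """Unordered species pairs whose minimum between-species K2P is < threshold (%).

    Returned as ``(species_a, species_b, min_distance_pct)`` sorted by
    distance then names.
    """
    blocks = _species_blocks(dm)
    names = sorted(blocks)
    out = []
    for a_i in range(len(names)):
        for b_i in range(a_i + 1, len(names)):
            a, b = names[a_i], names[b_i]
            inter = dm.d[np.ix_(blocks[a], blocks[b])]
            if not np.isfinite(inter).any():
                continue
            m = float(np.nanmin(inter)) * 100
            if m < threshold:
                out.append((a, b, m))
    return sorted(out, key=lambda t: (t[2], t[0], t[1]))


def distance_extremes(dm: DistanceMatrix) -> dict[str, float]:
    """Global min/max (in %) of intra- and interspecific defined distances."""
    if not dm.species:
        raise ValueError("distance matrix carries no species labels")
    sp = np.asarray(dm.species)
    iu, ju = np.triu_indices(len(dm), 1)
    vals = dm.d[iu, ju]
    same = sp[iu] == sp[ju]
    defined = ~np.isnan(vals)
    intra = vals[same & defined] * 100
    inter = vals[~same & defined] * 100
    return {
        "min_intra_pct": float(intra.min()) if intra.size else float("nan"),
        "max_intra_pct": float(intra.max()) if intra.size else float("nan"),
        "min_inter_pct": float(inter.min()) if inter.size else float("nan"),
        "max_inter_pct": float(inter.max()) if inter.size else float("nan"),
        "n_intra_pairs": int(intra.size),
        "n_inter_pairs": int(inter.size),
    }


def min_between_cluster_distances(
    dm: DistanceMatrix, partition: dict[str, str]
) -> pd.DataFrame:
    """QC helper: minimum distance between every pair of OTU clusters.

    Reports, for libraries where a "lowest distance between clearly
    distinct clusters" statement is wanted, both the species-level and
    cluster-level interpretations of that minimum.
    """
    labels = np.array([partition[i] for i in dm.ids])
    uniq = sorted(set(labels))
    rows = []
    for i in range(len(uniq)):
        for j in range(i + 1, len(uniq)):
            a = np.where(labels == uniq[i])[0]
            b = np.where(labels == uniq[j])[0]
            block = dm.d[np.ix_(a, b)]
            if np.isfinite(block).any():
                rows.append(
                    {
                        "cluster_a": uniq[i],
                        "cluster_b": uniq[j],
                        "min_distance_pct": float(np.nanmin(block)) * 100,
                    }
                )
    return pd.DataFrame(rows)


def summaries_to_frame(summaries: list[SpeciesSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.as_dict() for s in summaries])
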