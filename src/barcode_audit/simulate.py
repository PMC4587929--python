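"""Synthetic barcode-library generator with full ground truth.

Generates aligned CO1-like libraries whose statistical structure matches
what a large regional barcode survey looks like: many species with low
intraspecific variation, a long tail of singletons, a handful of species
carrying deep intraspecific splits, and (optionally) a recently diverged
species pair sharing haplotypes. Every engineered property is recorded
in truth tables so downstream analyses can be checked by parameter
recovery instead of against deposited data.

Construction is mutation-based, not coalescent: a root sequence drawn
from a target base composition; species founders placed by substitution
walks (transition:transversion ratio configurable) kept at least an
interspecific floor apart in *realized* K2P; specimens scattered around
their founder within the intraspecific target. Deep splits are built as
sub-founder clusters whose realized K2P depth crosses the requested
value; "chained" splits interpose intermediate clusters so that
single-linkage clustering at 2.2% keeps the species in one OTU while the
maximum intraspecific distance still exceeds the screening threshold.

Everything is driven by one integer seed; identical config + seed gives
byte-identical FASTA/TSV output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distance import k2p_distance
from .library import BarcodeLibrary, BarcodeRecord

_PURINE = {"A": "G", "G": "A"}
_PYRIMIDINE = {"C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}

_GENERA = (
    "Simulogammarus",
    "Fictocarcinus",
    "Pseudopagurus",
    "Synthocalanus",
    "Mimocrangon",
    "Apobalanus",
    "Spurioidotea",
    "Inventomysis",
)
_ORDERS = (
    "Amphipoda",
    "Decapoda",
    "Calanoida",
    "Harpacticoida",
    "Isopoda",
    "Sessilia",
    "Mysida",
    "Cumacea",
)


def _rng_of(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def mutate_sequence(
    seq: str,
    n_transitions: int,
    n_transversions: int,
    seed_or_rng,
    composition: tuple[float, float, float, float] | None = None,
) -> str:
    """Apply exact transition/transversion counts at distinct random sites.

    Only unambiguous A/C/G/T sites are eligible. This is the instrument
    used to verify K2P arithmetic: mutating k_s transitions and k_v
    transversions on an L-site sequence yields, against the original,
    exactly P = k_s/L and Q = k_v/L.

    When ``composition`` (A, C, G, T frequencies) is given, transversion
    targets are drawn proportionally to it instead of uniformly, which
    keeps heavily mutated sequences near the target base composition.
    """
    rng = _rng_of(seed_or_rng)
    total = n_transitions + n_transversions
    eligible = [i for i, c in enumerate(seq) if c in "ACGT"]
    if total > len(eligible):
        raise ValueError(
            f"requested {total} mutations but only {len(eligible)} eligible sites"
        )
    comp = dict(zip("ACGT", composition)) if composition else None
    out = list(seq)
    if comp is None:
        pos = rng.choice(len(eligible), size=total, replace=False)
        for k, p in enumerate(pos):
            i = eligible[p]
            base = out[i]
            if k < n_transitions:
                out[i] = _PURINE.get(base) or _PYRIMIDINE[base]
            else:
                out[i] = _TRANSVERSIONS[base][rng.integers(2)]
        return "".join(out)

    # composition-preserving variant: Metropolis-Hastings acceptance keeps
    # the target frequencies stationary under heavy mutation loads
    pool = list(eligible)
    pur = comp["A"] + comp["G"]
    pyr = comp["C"] + comp["T"]
    for k in range(total):
        for _ in range(10_000):
            j = int(rng.integers(len(pool)))
            i = pool[j]
            base = out[i]
            if k < n_transitions:
                target = _PURINE.get(base) or _PYRIMIDINE[base]
                ratio = comp[target] / comp[base]
            else:
                t1, t2 = _TRANSVERSIONS[base]
                w = comp[t1] / (comp[t1] + comp[t2])
                target = t1 if rng.random() < w else t2
                ratio = (pyr / pur) if base in _PURINE else (pur / pyr)
            if ratio >= 1 or rng.random() < ratio:
                out[i] = target
                pool[j] = pool[-1]
                pool.pop()
                break
        else:  # pragma: no cover
            raise RuntimeError("mutation proposal loop failed to accept")
    return "".join(out)


def _mutate_k(
    seq: str,
    k: int,
    ts_tv_ratio: float,
    rng: np.random.Generator,
    composition: tuple[float, float, float, float] | None = None,
) -> str:
    """k substitutions at distinct sites, each a transition with
    probability r/(r+1)."""
    p_ts = ts_tv_ratio / (ts_tv_ratio + 1.0)
    n_ts = int(rng.binomial(k, p_ts))
    return mutate_sequence(seq, n_ts, k - n_ts, rng, composition=composition)


@dataclass(frozen=True)
class DeepSplitSpec:
    """One engineered deep intraspecific split.

    ``otus`` is the number of threshold-2.2% single-linkage clusters the
    species should span: 1 means a chained split (consecutive clusters
    closer than 2.2% but total depth beyond it), 2 and 3 mean clearly
    separated sub-clusters.
    """

    depth_pct: float
    n_specimens: int
    otus: int = 2

    def __post_init__(self):
        if self.depth_pct <= 2.2:
            raise ValueError("deep split depth must exceed the 2.2% screening threshold")
        if self.otus not in (1, 2, 3):
            raise ValueError("otus must be 1, 2 or 3")
        if self.n_specimens < 2 * self.otus if self.otus > 1 else self.n_specimens < 3:
            raise ValueError("not enough specimens for the requested split shape")


#: depths/sizes/cluster counts for the default 13 deep-split species
#: (six single-OTU chained, six two-OTU, one three-OTU)
DEFAULT_DEEP_SPLITS = (
    DeepSplitSpec(2.36, 6, 1),
    DeepSplitSpec(2.66, 19, 1),
    DeepSplitSpec(2.89, 12, 1),
    DeepSplitSpec(2.99, 14, 1),
    DeepSplitSpec(4.00, 21, 1),
    DeepSplitSpec(4.43, 9, 1),
    DeepSplitSpec(3.41, 9, 2),
    DeepSplitSpec(3.81, 11, 2),
    DeepSplitSpec(4.78, 6, 2),
    DeepSplitSpec(4.79, 4, 2),
    DeepSplitSpec(6.11, 22, 2),
    DeepSplitSpec(14.87, 10, 2),
    DeepSplitSpec(4.14, 6, 3),
)


@dataclass(frozen=True)
class SharedPairSpec:
    """A recently diverged species pair sharing haplotypes.

    The default shape mirrors a two-species cluster of 9 + 7 specimens
    over 7 haplotypes, 2 of them shared; one specimen of species B sits
    alone on a shared haplotype otherwise occupied by species A, which
    forces exactly one non-singleton best-match error.
    """

    n_a: int = 9
    n_b: int = 7

    def __post_init__(self):
        if self.n_a < 5 or self.n_b < 6:
            raise ValueError("shared pair needs n_a >= 5 and n_b >= 6")


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_species: int = 205
    total_specimens: int = 1332
    n_singletons: int = 26
    max_specimens: int = 32
    seq_length: int = 600
    base_composition: tuple[float, float, float, float] = (0.26, 0.19, 0.19, 0.36)
    ts_tv_ratio: float = 2.0
    intraspecific_target: float = 1.0  # percent, max within-cluster scatter
    interspecific_target: float = 5.0  # percent, minimum between-species K2P
    deep_splits: tuple[DeepSplitSpec, ...] = DEFAULT_DEEP_SPLITS
    shared_pair: SharedPairSpec | None = SharedPairSpec()
    founder_substitutions: tuple[int, int] = (30, 120)

    def __post_init__(self):
        if self.intraspecific_target >= self.interspecific_target:
            raise ValueError(
                "intraspecific_target must be below interspecific_target"
            )
        if abs(sum(self.base_composition) - 1.0) > 1e-9:
            raise ValueError("base_composition must sum to 1")
        n_special = len(self.deep_splits) + (2 if self.shared_pair else 0)
        if self.n_species < n_special + self.n_singletons + 1:
            raise ValueError("n_species too small for the engineered structure")


@dataclass(frozen=True)
class SimulationResult:
    library: BarcodeLibrary
    config: SimulationConfig
    species_truth: pd.DataFrame  # species, n, category, depth, expected flags/OTUs
    shared_truth: dict  # engineered sharing-pair facts
    singleton_species: tuple[str, ...]

    @property
    def expected_flagged(self) -> list[str]:
        t = self.species_truth
        return sorted(t.loc[t["expected_flagged"], "species"])


def _draw_root(cfg: SimulationConfig, rng: np.random.Generator) -> str:
    """Root sequence with *exact* target base counts (largest-remainder
    apportionment, then a random shuffle): every founder inherits the
    root's composition, so sampling noise here would propagate to the
    whole library."""
    L = cfg.seq_length
    exact = np.array(cfg.base_composition) * L
    counts = np.floor(exact).astype(int)
    for i in np.argsort(-(exact - counts))[: L - counts.sum()]:
        counts[i] += 1
    bases = np.repeat(list("ACGT"), counts)
    return "".join(rng.permutation(bases))


def _k2p(a: str, b: str) -> float:
    d, _ = k2p_distance(a, b, min_overlap=1)
    return d * 100.0


def _grow_to_depth(
    base: str,
    target_pct: float,
    origin: str,
    ts_tv: float,
    rng: np.random.Generator,
    comp=None,
) -> str:
    """Mutate ``base`` until realized K2P(origin, result) first crosses
    ``target_pct``; overshoot is at most ~one substitution (~0.2 pp at
    600 bp)."""
    cur = base
    guard = 0
    while _k2p(origin, cur) < target_pct:
        cur = _mutate_k(cur, 1, ts_tv, rng, comp)
        guard += 1
        if guard > 10 * len(base):
            raise RuntimeError("deep-split construction failed to converge")
    return cur


def _far_enough(candidate: str, reps: list[str], floor_pct: float) -> bool:
    return all(_k2p(candidate, r) >= floor_pct for r in reps)


def _specimen_counts_rest(
    cfg: SimulationConfig, n_rest: int, budget: int, rng: np.random.Generator
) -> list[int]:
    """Right-skewed specimen counts for the unengineered species: one
    maximally sampled species, the rest >= 2, summing exactly to budget."""
    if n_rest == 0:
        return []
    if n_rest == 1:
        return [budget]
    counts = [min(cfg.max_specimens, budget - 2 * (n_rest - 1))]
    remaining = n_rest - 1
    body = 2 + rng.geometric(0.22, size=remaining) - 1
    body = np.clip(body, 2, cfg.max_specimens - 1).astype(int)
    counts.extend(body.tolist())
    # repair to the exact budget, deterministically
    def total():
        return sum(counts)

    i = 1
    while total() > budget:
        j = 1 + (i % (len(counts) - 1))
        if counts[j] > 2:
            counts[j] -= 1
        i += 1
    i = 1
    while total() < budget:
        j = 1 + (i % (len(counts) - 1))
        if counts[j] < cfg.max_specimens - 1:
            counts[j] += 1
        i += 1
    return counts


def _scatter(
    founder: str, n: int, max_muts: int, ts_tv: float, rng: np.random.Generator, comp=None
) -> list[str]:
    """Star-like cluster: each specimen 0..max_muts substitutions from
    the founder."""
    out = []
    for _ in range(n):
        k = int(rng.integers(0, max_muts + 1))
        out.append(_mutate_k(founder, k, ts_tv, rng, comp) if k else founder)
    return out


def _disjoint_positions_mutant(
    base: str, k: int, used: set[int], ts_tv: float, rng: np.random.Generator, comp=None
) -> tuple[str, set[int]]:
    """k substitutions at sites not in ``used``; returns mutant and its sites."""
    eligible = [i for i, c in enumerate(base) if c in "ACGT" and i not in used]
    pos = rng.choice(len(eligible), size=k, replace=False)
    sites = {eligible[p] for p in pos}
    out = list(base)
    p_ts = ts_tv / (ts_tv + 1.0)
    for i in sites:
        if rng.random() < p_ts:
            out[i] = _PURINE.get(out[i]) or _PYRIMIDINE[out[i]]
        else:
            t1, t2 = _TRANSVERSIONS[out[i]]
            if comp is None:
                out[i] = (t1, t2)[rng.integers(2)]
            else:
                w = comp[t1] / (comp[t1] + comp[t2])
                out[i] = t1 if rng.random() < w else t2
    return "".join(out), sites


def simulate_library(config: SimulationConfig) -> SimulationResult:
    """Generate the library and its ground truth (see module docstring)."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    root = _draw_root(cfg, rng)
    ts_tv = cfg.ts_tv_ratio
    # founders must clear the interspecific floor with headroom for the
    # +-2-substitution specimen scatter (~0.7 pp at 600 bp)
    floor_rep = cfg.interspecific_target + 0.7

    has_pair = cfg.shared_pair is not None
    # species roles, in a fixed deterministic order
    roles: list[tuple[str, dict]] = []
    for spec in cfg.deep_splits:
        roles.append(("deep_split", {"spec": spec}))
    if has_pair:
        roles.append(("shared_a", {}))
        roles.append(("shared_b", {}))
    for _ in range(cfg.n_singletons):
        roles.append(("singleton", {}))
    n_rest = cfg.n_species - len(roles)
    engineered_specimens = (
        sum(s.n_specimens for s in cfg.deep_splits)
        + (cfg.shared_pair.n_a + cfg.shared_pair.n_b if has_pair else 0)
        + cfg.n_singletons
    )
    rest_budget = cfg.total_specimens - engineered_specimens
    if rest_budget < 2 * n_rest:
        raise ValueError("total_specimens too small for the engineered structure")
    rest_counts = _specimen_counts_rest(cfg, n_rest, rest_budget, rng)
    for c in rest_counts:
        roles.append(("normal", {"n": int(c)}))

    # deterministic naming
    species_names = []
    for i in range(len(roles)):
        genus = _GENERA[i % len(_GENERA)]
        species_names.append(f"{genus} sp{i + 1:03d}")
    orders = [_ORDERS[i % len(_ORDERS)] for i in range(len(roles))]

    # founders: shared pair uses one founder for both species
    reps: list[str] = []  # all cluster representatives, for floor checks
    founders: list[str] = []
    pair_founder: str | None = None
    lo, hi = cfg.founder_substitutions
    for i, (role, info) in enumerate(roles):
        if role == "shared_b":
            founders.append(pair_founder)  # same haplotype pool as shared_a
            continue
        for _attempt in range(200):
            k = int(rng.integers(lo, hi + 1))
            cand = _mutate_k(root, k, ts_tv, rng, cfg.base_composition)
            if _far_enough(cand, reps, floor_rep):
                break
        else:
            raise RuntimeError("could not place a founder beyond the interspecific floor")
        founders.append(cand)
        reps.append(cand)
        if role == "shared_a":
            pair_founder = cand

    # specimens
    scatter_muts = int(round(cfg.intraspecific_target / 100 * cfg.seq_length / 2))
    records: list[BarcodeRecord] = []
    truth_rows = []
    shared_truth: dict = {}
    singleton_names: list[str] = []
    next_id = 1

    def add(species_i: int, seq: str):
        nonlocal next_id
        records.append(
            BarcodeRecord(
                specimen_id=f"SIM{next_id:04d}",
                species=species_names[species_i],
                sequence=seq,
                taxonomy=("Malacostraca", orders[species_i]),
                locality="simulated shelf sea",
            )
        )
        next_id += 1
        return records[-1].specimen_id

    for i, (role, info) in enumerate(roles):
        name = species_names[i]
        founder = founders[i]
        if role == "singleton":
            add(i, founder)
            singleton_names.append(name)
            truth_rows.append(
                dict(species=name, n=1, category="singleton",
                     split_depth_pct=np.nan, expected_flagged=False, expected_n_otus=1)
            )
        elif role == "normal":
            n = info["n"]
            for seq in _scatter(founder, n, scatter_muts, ts_tv, rng, cfg.base_composition):
                add(i, seq)
            truth_rows.append(
                dict(species=name, n=n, category="normal",
                     split_depth_pct=np.nan, expected_flagged=False, expected_n_otus=1)
            )
        elif role == "deep_split":
            spec: DeepSplitSpec = info["spec"]
            clusters = _build_split_clusters(
                founder, spec, ts_tv, rng,
                reps_other=[r for r in reps if r != founder],
                floor_pct=floor_rep,
                comp=cfg.base_composition,
            )
            reps.extend(c for c in clusters[1:])
            sizes = _split_sizes(spec, len(clusters))
            for cl_seq, cl_n in zip(clusters, sizes):
                for _ in range(cl_n):
                    add(i, cl_seq)  # clusters are exact copies: depth is controlled
            truth_rows.append(
                dict(species=name, n=spec.n_specimens, category="deep_split",
                     split_depth_pct=spec.depth_pct, expected_flagged=True,
                     expected_n_otus=spec.otus)
            )
        elif role == "shared_a":
            pair = cfg.shared_pair
            haplos, used = {}, set()
            haplos["h1"] = founder
            comp_d = dict(zip("ACGT", cfg.base_composition))
            haplos["h2"], s2 = _disjoint_positions_mutant(founder, 3, used, ts_tv, rng, comp_d)
            used |= s2
            haplos["pa"], s3 = _disjoint_positions_mutant(founder, 3, used, ts_tv, rng, comp_d)
            used |= s3
            for b_i, kk in enumerate((2, 3, 2, 3), start=1):
                haplos[f"pb{b_i}"], sk = _disjoint_positions_mutant(
                    founder, kk, used, ts_tv, rng, comp_d
                )
                used |= sk
            # species A: bulk on h1, 3 on h2, 1 private
            for _ in range(pair.n_a - 4):
                add(i, haplos["h1"])
            for _ in range(3):
                add(i, haplos["h2"])
            add(i, haplos["pa"])
            # species B: bulk on h1, 1 alone on h2 (the forced best-match
            # error: its zero-distance matches are all species A), 4 privates
            bi = i + 1
            for _ in range(pair.n_b - 5):
                add(bi, haplos["h1"])
            lone_b = add(bi, haplos["h2"])
            for k in range(1, 5):
                add(bi, haplos[f"pb{k}"])
            shared_truth = {
                "species_a": name,
                "species_b": species_names[bi],
                "n_a": pair.n_a,
                "n_b": pair.n_b,
                "n_haplotypes": 7,
                "n_shared_haplotypes": 2,
                "expected_nonsingleton_bm_errors": 1,
                "bm_error_specimens": (lone_b,),
            }
            for nm, nn in ((name, pair.n_a), (species_names[bi], pair.n_b)):
                truth_rows.append(
                    dict(species=nm, n=nn, category="shared_pair",
                         split_depth_pct=np.nan, expected_flagged=False,
                         expected_n_otus=1)
                )
        elif role == "shared_b":
            continue  # emitted together with shared_a
        else:  # pragma: no cover
            raise AssertionError(role)

    library = BarcodeLibrary(tuple(records))
    assert len(library) == cfg.total_specimens, (len(library), cfg.total_specimens)
    return SimulationResult(
        library=library,
        config=cfg,
        species_truth=pd.DataFrame(truth_rows),
        shared_truth=shared_truth,
        singleton_species=tuple(singleton_names),
    )


def _split_sizes(spec: DeepSplitSpec, n_clusters: int) -> list[int]:
    n = spec.n_specimens
    if n_clusters == 1:
        return [n]
    if spec.otus == 1:
        # chain: bulk at the founder, at least one specimen per way-point
        sizes = [1] * n_clusters
        sizes[0] += n - n_clusters
        return sizes
    base = n // n_clusters
    sizes = [base] * n_clusters
    for k in range(n - base * n_clusters):
        sizes[k] += 1
    return sizes


def _build_split_clusters(
    founder: str,
    spec: DeepSplitSpec,
    ts_tv: float,
    rng: np.random.Generator,
    reps_other: list[str],
    floor_pct: float,
    comp=None,
) -> list[str]:
    """Sub-founder sequences implementing the requested split shape.

    The new sub-founders must respect the same interspecific floor as
    the founders so a deep split never lands closer to another species
    than to its own; the construction retries with fresh draws until it
    does (the 600-dimensional sequence space makes collisions rare).
    """
    for _attempt in range(50):
        if spec.otus == 1:
            # chained: way-points well below 2.2% apart up to the full
            # depth (1.5%-steps leave slack for mutation-site collisions)
            n_seg = max(2, int(np.ceil(spec.depth_pct / 1.5)))
            targets = [spec.depth_pct * (k + 1) / n_seg for k in range(n_seg)]
            clusters = [founder]
            cur = founder
            for t in targets:
                cur = _grow_to_depth(cur, t, founder, ts_tv, rng, comp)
                clusters.append(cur)
        elif spec.otus == 2:
            far = _grow_to_depth(founder, spec.depth_pct, founder, ts_tv, rng, comp)
            clusters = [founder, far]
        else:  # three clusters, mutually beyond the screening threshold
            far = _grow_to_depth(founder, spec.depth_pct, founder, ts_tv, rng, comp)
            mid = _grow_to_depth(founder, 0.7 * spec.depth_pct, founder, ts_tv, rng, comp)
            if _k2p(far, mid) <= 2.5:
                continue
            clusters = [founder, far, mid]
        if all(_k2p(c, r) >= floor_pct for c in clusters[1:] for r in reps_other):
            return clusters
    raise RuntimeError("could not place deep-split clusters beyond the interspecific floor")
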