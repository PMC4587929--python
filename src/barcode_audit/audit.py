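"""End-to-end library audit: one call producing the full report bundle.

Runs, in order: distance matrix, base composition, barcoding-gap
screening, threshold OTU clustering + concordance, data-driven threshold
selection, identification simulation (with and without singletons), the
NJ tree (with bootstrap support on a configurable taxon subset), and
haplotype networks for every species pair showing low interspecific
distances. All numbers in the summary reports are written from the same
persisted intermediates, and a JSON manifest records parameters, seed
and input checksums.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clustering import assignments_to_frame, concordance, threshold_clusters
from .distance import base_composition, pairwise_matrix, write_matrix_tsv
from .gap_analysis import (
    distance_extremes,
    flag_species,
    low_interspecific_pairs,
    min_between_cluster_distances,
    species_summaries,
    summaries_to_frame,
)
from .haplonet import (
    collapse_haplotypes,
    haplotype_membership_frame,
    parsimony_network,
    shared_haplotypes,
)
from .identification import outcomes_to_frame, run_simulation, tallies_to_frame
from .library import BarcodeLibrary, library_to_strings
from .njtree import bootstrap_support, nj_tree, write_newick
from .thresholds import cumulative_error_scan, density_local_minimum


@dataclass
class RunConfig:
    """Parameters of a full audit run."""

    outdir: str
    seed: int = 0
    screening_threshold: float = 2.2  # percent
    base_id_threshold: float = 1.0  # percent, engine-style default
    bootstrap_replicates: int = 1000
    bootstrap_taxa: tuple[str, ...] | None = None  # None = whole library
    max_steps: int = 25
    min_overlap: int = 100
    compute_tree: bool = True
    density_max_pairs: int | None = None

    def __post_init__(self):
        if self.screening_threshold <= 0 or self.base_id_threshold <= 0:
            raise ValueError("thresholds must be positive percentages")


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()


def run_full_audit(library: BarcodeLibrary, config: RunConfig) -> dict:
    """Run every analysis stage and persist the report bundle.

    Returns a summary dict (also written as ``summary.json``). On stage
    failure, partial outputs stay on disk under a ``failed/<stage>``
    marker and :class:`StageFailure` is raised.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"n_specimens": len(library), "n_species": len(set(library.species_labels))}
    stage = "setup"

    def enter(name: str):
        nonlocal stage
        stage = name

    try:
        enter("distance_matrix")
        dm = pairwise_matrix(library, min_overlap=config.min_overlap)
        write_matrix_tsv(dm, out / "matrix.tsv")
        summary["n_undefined_pairs"] = len(dm.undefined_pairs)

        enter("base_composition")
        comp = base_composition(library)
        summary["base_composition_pct"] = {b: round(100 * f, 2) for b, f in comp.items()}

        enter("gap_analysis")
        summ = species_summaries(dm, threshold=config.screening_threshold)
        summaries_to_frame(summ).to_csv(out / "species_summaries.tsv", sep="\t", index=False)
        flagged = flag_species(summ, threshold=config.screening_threshold)
        summaries_to_frame(flagged).to_csv(out / "flagged_species.tsv", sep="\t", index=False)
        low = low_interspecific_pairs(dm, threshold=config.screening_threshold)
        pd.DataFrame(low, columns=["species_a", "species_b", "min_distance_pct"]).to_csv(
            out / "low_interspecific_pairs.tsv", sep="\t", index=False
        )
        extremes = distance_extremes(dm)
        summary.update(
            n_flagged_species=len(flagged),
            flagged_species=[s.species for s in flagged],
            n_low_interspecific_pairs=len(low),
            distance_extremes_pct=extremes,
        )

        enter("otu_clustering")
        part = threshold_clusters(dm, config.screening_threshold)
        assignments_to_frame(part, library).to_csv(out / "otu_assignments.tsv", sep="\t", index=False)
        # QC: the "lowest distance between distinct clusters" statistic has a
        # species-level reading (nn_distance in species_summaries) and a
        # cluster-level one; persist the latter so both are inspectable
        min_between_cluster_distances(dm, part.assignment).to_csv(
            out / "between_otu_minima.tsv", sep="\t", index=False
        )
        conc = concordance(part, library)
        conc.to_frame().to_csv(out / "concordance.tsv", sep="\t", index=False)
        summary.update(
            n_otus=part.n_otus,
            n_species_1otu=conc.n_species_1otu,
            n_species_2otu=conc.n_species_2otu,
            n_species_3otu=conc.n_species_3otu,
            n_species_more_otus=conc.n_species_more,
            n_otus_shared=len(conc.otus_shared_by_multiple_species),
        )

        enter("threshold_selection")
        scan = cumulative_error_scan(dm)
        scan.to_frame().to_csv(out / "threshold_scan.tsv", sep="\t", index=False)
        dens = density_local_minimum(
            dm, max_pairs=config.density_max_pairs, seed=config.seed
        )
        dens.to_frame().to_csv(out / "distance_density.tsv", sep="\t", index=False)
        t_opt = scan.optimum
        t_min = dens.threshold
        summary["threshold_optimized_pct"] = t_opt
        summary["threshold_density_pct"] = t_min
        id_thresholds = [config.base_id_threshold, t_opt]
        if t_min is not None:
            id_thresholds.append(round(t_min, 1))
        id_thresholds = sorted(set(round(t, 4) for t in id_thresholds))

        enter("identification_simulation")
        blocks = []
        for excl in (False, True):
            tallies, outcomes = run_simulation(
                dm, thresholds=id_thresholds, exclude_singletons=excl
            )
            blocks.append(tallies_to_frame(tallies))
            suffix = "excl_singletons" if excl else "with_singletons"
            outcomes_to_frame(outcomes).to_csv(
                out / f"identification_outcomes_{suffix}.tsv", sep="\t", index=False
            )
            summary[f"identification_{suffix}"] = [t.as_dict() for t in tallies]
        pd.concat(blocks).to_csv(out / "identification_summary.tsv", sep="\t", index=False)

        if config.compute_tree:
            enter("nj_tree")
            tree = nj_tree(dm)
            write_newick(tree, str(out / "nj_tree.nwk"))
            if config.bootstrap_replicates > 0:
                boot_lib = library
                if config.bootstrap_taxa is not None:
                    boot_lib = library.subset(config.bootstrap_taxa)
                btree = bootstrap_support(
                    boot_lib,
                    replicates=config.bootstrap_replicates,
                    seed=config.seed,
                    min_overlap=config.min_overlap,
                )
                write_newick(btree, str(out / "nj_tree_bootstrap.nwk"))
                summary["bootstrap_replicates"] = config.bootstrap_replicates
                summary["bootstrap_dropped_replicates"] = btree.n_dropped_replicates

        enter("haplotype_networks")
        networks = []
        for a, b, dist in low:
            sub = library.subset_species([a, b])
            haps, held = collapse_haplotypes(sub)
            net = parsimony_network(haps, max_steps=config.max_steps)
            tag = f"network_{len(networks) + 1:02d}"
            net.nodes_frame().to_csv(out / f"{tag}_nodes.tsv", sep="\t", index=False)
            net.edges_frame().to_csv(out / f"{tag}_edges.tsv", sep="\t", index=False)
            haplotype_membership_frame(haps, held).to_csv(
                out / f"{tag}_membership.tsv", sep="\t", index=False
            )
            networks.append(
                {
                    "species": [a, b],
                    "min_distance_pct": dist,
                    "n_haplotypes": len(haps),
                    "n_shared_haplotypes": len(shared_haplotypes(haps)),
                    "n_held_out": len(held),
                    "files": tag,
                }
            )
        summary["haplotype_networks"] = networks

        enter("manifest")
        fasta_text, meta_text = library_to_strings(library)
        manifest = {
            "package_version": __version__,
            "python": platform.python_version(),
            "config": {
                **asdict(config),
                "bootstrap_taxa": list(config.bootstrap_taxa)
                if config.bootstrap_taxa
                else None,
            },
            "input_checksums": {
                "fasta_sha256": _sha256(fasta_text),
                "metadata_sha256": _sha256(meta_text),
            },
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True, default=str))
        return summary
    except Exception as exc:
        failed = out / "failed"
        failed.mkdir(exist_ok=True)
        (failed / stage).write_text(repr(exc))
        raise StageFailure(stage, exc) from exc
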