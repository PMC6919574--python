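"""End-to-end orchestration: load -> normalize -> assign -> structure ->
diversity -> clones/dispersal/temporal, with a reproducibility manifest.

A run is configured by one JSON/dict config; every stochastic stage
(imputation tie-breaks, the 2N constraint, bootstraps) derives its seed
from the config's master seed, so a rerun with the same config reproduces
byte-identical outputs.  The manifest records the config, seeds, input
checksum and per-output checksums.

Config keys (all optional unless noted)::

    input_csv      path to an isolate CSV  (or "simulate": {...} instead)
    refs_csv       path to a reference-panel CSV (defaults to the
                   simulation founders when simulating)
    seed           master seed (default 0)
    n_boot         bootstrap replicates (default 100)
    normalize      {"control": strain_id, "reference_plate": plate_id}
    constrain_2n   also run the 2N-constrained control analysis (bool)
    n_axes         MST axes (default 2)
    simulate       {"scale": fraction} generate input with the synthetic
                   module at the given size fraction of the default cohort
    plots          write PNG figures (bool, default false)
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

from . import __version__
from .genotype_io import (
    IsolateTable,
    PlateControl,
    drop_plate_controls,
    missing_fraction,
    normalize_plates,
    read_isolates,
    write_isolates,
)
from .group_assignment import assign_groups, read_reference_panel, write_reference_panel
from .structure import (
    clustering_concordance,
    constrain_to_2n,
    encode_alleles,
    impute_missing_nn,
    minimum_spanning_tree,
    run_pca,
)
from .diversity import diversity_report, write_diversity_report
from .spatiotemporal import (
    bin_distances,
    clone_pair_distances,
    find_clone_groups,
    region_group_distribution,
    sample_group_diversity,
    temporal_group_proportions,
    winery_persistence,
)
from .synthetic import SimulationConfig, simulate_population, write_truth

logger = logging.getLogger(__name__)

__all__ = ["RunManifest", "run_all", "synthetic_recovery_experiment"]


def synthetic_recovery_experiment(
    cfg: Optional[SimulationConfig] = None, seed: int = 1, n_boot: int = 100
) -> dict:
    """Generate a study-scale synthetic cohort and measure how well the
    pipeline recovers its planted structure.

    Runs generation -> plate normalization -> group assignment -> clone
    detection -> temporal proportions, comparing each stage's output with
    the generator's ground truth.  Returns a dict with: assignment accuracy
    (fraction of isolates recovering their planted group), plate-offset
    recovery rate, whether the clone partition on the complete-genotype
    subset equals the planted partition, the earliest vintage of any
    putative-triploid isolate, the self-coverage of the temporal bootstrap
    CIs, and the realized missing-cell fraction.
    """
    from collections import defaultdict

    import numpy as np

    from .genotype_io import genotype_is_complete
    from .group_assignment import assign_groups as _assign

    cfg = cfg or SimulationConfig()
    table, truth = simulate_population(cfg, seed=seed)
    control = cfg.plate_control()

    from .genotype_io import plate_offsets as _offsets

    recovered_offsets = _offsets(table, control)
    n_off = len(truth.plate_offsets)
    offset_rate = sum(
        recovered_offsets.get(k) == v for k, v in truth.plate_offsets.items()
    ) / n_off

    clean = drop_plate_controls(normalize_plates(table, control), control)
    truth_group = dict(zip(truth.isolates["strain_id"], truth.isolates["true_group"]))
    assignments = _assign(clean, truth.founders)
    accuracy = float(
        np.mean([a.group_name == truth_group[a.strain_id] for a in assignments])
    )

    truth_key = dict(
        zip(truth.isolates["strain_id"], truth.isolates["true_genotype_key"])
    )
    complete = {r.strain_id for r in clean if genotype_is_complete(r.genotype)}
    planted = defaultdict(set)
    for sid in complete:
        planted[truth_key[sid]].add(sid)
    planted_partition = {frozenset(v) for v in planted.values() if len(v) >= 2}
    recovered_partition = {frozenset(g.members) for g in find_clone_groups(clean)}
    partition_exact = recovered_partition == planted_partition

    triploid_groups = {g.name for g in truth.founders if g.ploidy == 3}
    earliest_triploid = min(
        r.vintage_year for r in clean if truth_group[r.strain_id] in triploid_groups
    )

    temporal = temporal_group_proportions(clean, n_boot=n_boot, seed=seed)
    ci_cover = float(
        ((temporal["proportion"] >= temporal["ci_low"])
         & (temporal["proportion"] <= temporal["ci_high"])).mean()
    )

    return {
        "n_isolates": len(truth.isolates),
        "assignment_accuracy": accuracy,
        "plate_offset_recovery_rate": offset_rate,
        "clone_partition_exact": partition_exact,
        "earliest_triploid_vintage": int(earliest_triploid),
        "temporal_ci_self_coverage": ci_cover,
        "missing_cell_fraction": missing_fraction(
            clean.subset(truth.isolates["strain_id"].tolist())
        ),
    }


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    version: str
    config: dict
    seed: int
    started: str
    finished: Optional[str] = None
    input_sha256: Optional[str] = None
    outputs: Dict[str, dict] = field(default_factory=dict)
    stages: Dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _register(manifest: RunManifest, name: str, path: Path) -> None:
    manifest.outputs[name] = {"path": str(path), "sha256": _sha256(path)}


def run_all(config, out_dir) -> RunManifest:
    """Run the full analysis described by *config* into *out_dir*.

    *config* is a dict or a path to a JSON file.  Raises on stage failure
    after writing a manifest that marks the failed stage; partial outputs
    are retained.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = json.load(fh)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    n_boot = int(config.get("n_boot", 100))
    manifest = RunManifest(
        version=__version__,
        config=config,
        seed=seed,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    stage = "setup"
    try:
        # --- input -----------------------------------------------------------
        refs = None
        if "simulate" in config:
            stage = "simulate"
            sim_cfg = SimulationConfig()
            scale = float(config["simulate"].get("scale", 1.0))
            if scale < 1.0:
                sim_cfg = sim_cfg.scaled(scale)
            table, truth = simulate_population(sim_cfg, seed=seed)
            input_csv = out / "simulated_isolates.csv"
            write_isolates(table, input_csv)
            write_truth(truth, out / "truth_isolates.csv", out / "truth_offsets.json")
            _register(manifest, "simulated_isolates", input_csv)
            _register(manifest, "truth_isolates", out / "truth_isolates.csv")
            refs = truth.founders
            refs_csv = out / "references.csv"
            write_reference_panel(refs, refs_csv)
            _register(manifest, "references", refs_csv)
            control = sim_cfg.plate_control()
        else:
            input_csv = Path(config["input_csv"])
            control = None
            if "normalize" in config:
                control = PlateControl(
                    config["normalize"]["control"],
                    config["normalize"]["reference_plate"],
                )
        stage = "load"
        manifest.input_sha256 = _sha256(Path(input_csv))
        table = read_isolates(input_csv)
        if refs is None:
            refs = read_reference_panel(config["refs_csv"], table.panel)

        # --- normalize -------------------------------------------------------
        if control is not None:
            stage = "normalize"
            table = normalize_plates(table, control)
            table = drop_plate_controls(table, control)
            clean_csv = out / "normalized_isolates.csv"
            write_isolates(table, clean_csv)
            _register(manifest, "normalized_isolates", clean_csv)
        logger.info("analysing %d isolates (%.1f%% missing cells)",
                    len(table), 100 * missing_fraction(table))

        # --- assignment ------------------------------------------------------
        stage = "assign"
        assign_groups(table, refs)
        assigned_csv = out / "assigned_isolates.csv"
        write_isolates(table, assigned_csv)
        _register(manifest, "assigned_isolates", assigned_csv)

        # --- diversity -------------------------------------------------------
        stage = "diversity"
        report = diversity_report(table, n_boot=n_boot, seed=seed,
                                  group_order=refs.group_names())
        write_diversity_report(report, out / "diversity.csv")
        _register(manifest, "diversity", out / "diversity.csv")

        # --- structure -------------------------------------------------------
        stage = "structure"
        n_axes = int(config.get("n_axes", 2))
        imputed = impute_missing_nn(table, seed=seed)
        pca = run_pca(encode_alleles(imputed), n_components=max(n_axes, 2))
        pca.coordinates.to_csv(out / "pca_scores.tsv", sep="\t")
        _register(manifest, "pca_scores", out / "pca_scores.tsv")
        tree = minimum_spanning_tree(pca, n_axes=n_axes)
        tree.to_frame().to_csv(out / "mst_edges.tsv", sep="\t", index=False)
        _register(manifest, "mst_edges", out / "mst_edges.tsv")

        # --- clones / dispersal / temporal -----------------------------------
        stage = "clones"
        groups = find_clone_groups(table)
        import pandas as pd
        pd.DataFrame(
            [
                {
                    "clone_id": g.clone_id,
                    "size": g.size,
                    "members": ";".join(g.members),
                    "wineries": ";".join(sorted(g.wineries)),
                    "countries": ";".join(sorted(g.countries)),
                    "vintages": ";".join(map(str, g.vintages)),
                }
                for g in groups
            ]
        ).to_csv(out / "clone_groups.csv", index=False)
        _register(manifest, "clone_groups", out / "clone_groups.csv")

        persistence = winery_persistence(groups, table)
        pd.DataFrame(
            [
                {
                    "winery": r.winery,
                    "clone_id": r.clone_id,
                    "vintages": ";".join(map(str, r.vintages)),
                    "interval_years": r.interval_years,
                }
                for r in persistence
            ]
        ).to_csv(out / "persistence.csv", index=False)
        _register(manifest, "persistence", out / "persistence.csv")

        pairs = clone_pair_distances(groups, table)
        pd.DataFrame(pairs, columns=["clone_id", "km"]).to_csv(
            out / "clone_pair_distances.tsv", sep="\t", index=False
        )
        _register(manifest, "clone_pair_distances", out / "clone_pair_distances.tsv")
        classes = bin_distances([km for _, km in pairs])
        (out / "distance_classes.json").write_text(
            json.dumps(classes.to_dict(), indent=1, sort_keys=True)
        )
        _register(manifest, "distance_classes", out / "distance_classes.json")

        region_group_distribution(table, by="region").to_csv(
            out / "region_groups.csv", index=False
        )
        _register(manifest, "region_groups", out / "region_groups.csv")
        samples = sample_group_diversity(table)
        samples.per_sample.to_csv(out / "sample_diversity.csv", index=False)
        _register(manifest, "sample_diversity", out / "sample_diversity.csv")

        stage = "temporal"
        temporal = temporal_group_proportions(table, n_boot=n_boot, seed=seed)
        temporal.to_csv(out / "temporal_proportions.csv", index=False)
        _register(manifest, "temporal_proportions", out / "temporal_proportions.csv")

        # --- 2N-constrained control ------------------------------------------
        if config.get("constrain_2n"):
            stage = "constrain_2n"
            constrained = constrain_to_2n(table, seed=seed)
            full_assign = assign_groups(table, refs)
            con_assign = assign_groups(constrained, refs)
            concordance = clustering_concordance(full_assign, con_assign)
            (out / "concordance.json").write_text(
                json.dumps(
                    {
                        "overall": concordance.overall,
                        "per_group": concordance.per_group,
                        "n": concordance.n,
                    },
                    indent=1, sort_keys=True,
                )
            )
            _register(manifest, "concordance", out / "concordance.json")
            imputed_c = impute_missing_nn(constrained, seed=seed)
            pca_c = run_pca(encode_alleles(imputed_c), n_components=max(n_axes, 2))
            pca_c.coordinates.to_csv(out / "pca_scores_2n.tsv", sep="\t")
            _register(manifest, "pca_scores_2n", out / "pca_scores_2n.tsv")
            tree_c = minimum_spanning_tree(pca_c, n_axes=n_axes)
            tree_c.to_frame().to_csv(out / "mst_edges_2n.tsv", sep="\t", index=False)
            _register(manifest, "mst_edges_2n", out / "mst_edges_2n.tsv")

        # --- plots -----------------------------------------------------------
        if config.get("plots"):
            stage = "plots"
            from .structure import plot_mst
            from .spatiotemporal import plot_distance_classes, plot_temporal_proportions

            labels = {rec.strain_id: rec.group_label or "?" for rec in table}
            sizes: Dict[str, int] = {}
            for g in groups:
                for sid in g.members:
                    sizes[sid] = g.size
            plot_mst(pca, tree, out / "mst.png", group_labels=labels, clone_sizes=sizes)
            _register(manifest, "mst_plot", out / "mst.png")
            plot_distance_classes(classes, out / "distance_classes.png")
            _register(manifest, "distance_classes_plot", out / "distance_classes.png")
            if len(temporal):
                plot_temporal_proportions(temporal, out / "temporal.png")
                _register(manifest, "temporal_plot", out / "temporal.png")

        manifest.stages = {s: "ok" for s in (
            "load", "normalize", "assign", "diversity", "structure",
            "clones", "temporal",
        )}
    except Exception as exc:
        manifest.stages[stage] = f"failed: {exc}"
        manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
        (out / "manifest.json").write_text(manifest.to_json())
        logger.error("stage %s failed: %s", stage, exc)
        raise
    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
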