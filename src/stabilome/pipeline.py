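"""End-to-end orchestration: normalize -> diversity -> AVD -> betaNTI -> networks -> importance.

One global seed fans out to per-stage seeds through ``numpy.random.SeedSequence
(seed).spawn``, so each stage is independently reproducible. Every output file
is a TSV under one run directory, recorded with its SHA-256 hash in a JSON run
manifest together with the configuration snapshot and stage warnings. A stage
that cannot run (e.g. betaNTI without a tree) is skipped with an explicit
reason; downstream stages that do not depend on it still execute.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from stabilome import conet
from stabilome.io_model import AnalysisConfig, CountTable, SampleMetadata, write_count_table
from stabilome.ml_importance import discretize_target, mean_decrease_accuracy
from stabilome.normalization import NormalizationSpec, relative_abundance
from stabilome.phylo import bnti, faith_pd
from stabilome.stability import avd_by_group, avd_summary_frame

__all__ = ["RunManifest", "run_pipeline", "stage_seeds"]


def stage_seeds(seed: int, n: int = 8) -> list[int]:
    """Deterministic per-stage child seeds (< 2^31) from one global seed."""
    return [int(c.generate_state(1)[0] % (2**31 - 1))
            for c in np.random.SeedSequence(seed).spawn(n)]


@dataclass
class RunManifest:
    seed: int
    config: dict
    stages: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    def record(self, stage: str, outputs: dict[str, Path], status: str = "ok",
               reason: str = "") -> None:
        self.stages.append({
            "stage": stage,
            "status": status,
            "reason": reason,
            "outputs": {name: {"path": str(p), "sha256": _sha256(p)}
                        for name, p in outputs.items()},
        })

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(
            {"seed": self.seed, "config": self.config, "stages": self.stages,
             "warnings": self.warnings}, indent=2))


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _dilution_groups(metadata: SampleMetadata) -> dict[str, list]:
    return SampleMetadata(metadata.table.copy(), grouping_key="dilution").groups()


def run_pipeline(
    config: AnalysisConfig,
    counts: CountTable,
    metadata: SampleMetadata,
    outdir: str | Path,
    tree: TreeNode | None = None,
    functional: CountTable | None = None,
    bnti_replicates_per_ph: int = 2,
) -> tuple[RunManifest, dict]:
    """Run every analysis stage on the given inputs and write one run directory.

    Returns the manifest and an in-memory report dict with the per-stage
    tables. ``bnti_replicates_per_ph`` bounds the betaNTI stage (which is
    quadratic in samples) to the first few replicates of each pH level.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    metadata.require_cover(counts)
    manifest = RunManifest(seed=config.seed, config=config.to_dict())
    seeds = stage_seeds(config.seed)
    report: dict = {}

    # -- normalization ------------------------------------------------------
    norm = NormalizationSpec("rarefy", depth=config.rarefaction_depth, seed=seeds[0])
    from stabilome.normalization import rarefy

    rar = rarefy(counts, norm.depth, norm.seed)
    if rar.dropped_samples:
        manifest.warnings.append(
            f"rarefaction dropped {len(rar.dropped_samples)} samples: "
            f"{rar.dropped_samples[:5]}"
        )
    rarefied = rar.table
    p = outdir / "rarefied_counts.tsv"
    write_count_table(rarefied, p)
    manifest.record("normalize", {"rarefied_counts": p})

    # -- diversity ----------------------------------------------------------
    richness = pd.Series((rarefied.values > 0).sum(axis=0), index=rarefied.samples,
                         name="richness")
    div = pd.DataFrame({"richness": richness})
    if tree is not None:
        div["faith_pd"] = faith_pd(rarefied, tree)
    p = outdir / "alpha_diversity.tsv"
    div.to_csv(p, sep="\t", index_label="sample")
    report["alpha_diversity"] = div
    manifest.record("diversity", {"alpha_diversity": p})

    # -- AVD ----------------------------------------------------------------
    avd_results = avd_by_group(rarefied, metadata)
    avd_frame = avd_summary_frame(avd_results)
    avd_frame["normalization"] = f"rarefy:{config.rarefaction_depth}"
    p = outdir / "avd_by_group.tsv"
    avd_frame.to_csv(p, sep="\t", index=False)
    report["avd"] = avd_frame
    sample_score = pd.concat([r.deviations.mean(axis=0) for r in avd_results.values()])
    sample_score.name = "mean_variation_degree"
    p2 = outdir / "sample_variation.tsv"
    sample_score.to_csv(p2, sep="\t", index_label="sample")
    report["sample_variation"] = sample_score
    manifest.record("avd", {"avd_by_group": p, "sample_variation": p2})

    # -- betaNTI ------------------------------------------------------------
    if tree is None:
        manifest.record("bnti", {}, status="skipped", reason="no tree input")
    else:
        rows = []
        groups = _dilution_groups(metadata)
        for label, samples in groups.items():
            sub_meta = metadata.table.loc[[s for s in samples if s in rarefied.data.columns]]
            chosen = (
                sub_meta.sort_values(["pH", "replicate"])
                .groupby("pH", sort=True)
                .head(bnti_replicates_per_ph)
            )
            ids = list(chosen.index)
            if len(ids) < 3:
                continue
            sub = rarefied.subset_samples(ids)
            sub = CountTable(sub.data.loc[(sub.values > 0).any(axis=1)])
            res = bnti(sub, tree, n_null=config.bnti_null_draws, seed=seeds[1])
            lf = res.long_frame()
            lf.insert(0, "group", label)
            ph = metadata.table["pH"]
            lf["between_ph"] = [
                ph[a] != ph[b] for a, b in zip(lf["sample_a"], lf["sample_b"])
            ]
            rows.append(lf)
        bnti_frame = pd.concat(rows, ignore_index=True)
        p = outdir / "bnti_pairs.tsv"
        bnti_frame.to_csv(p, sep="\t", index=False)
        report["bnti"] = bnti_frame
        manifest.record("bnti", {"bnti_pairs": p})

    # -- functional co-occurrence networks ----------------------------------
    if functional is None:
        manifest.record("conet", {}, status="skipped", reason="no functional table")
    else:
        metadata.require_cover(functional)
        topo_rows, role_frames = [], []
        for label, samples in _dilution_groups(metadata).items():
            sub = functional.subset_samples(samples)
            sub = relative_abundance(CountTable(sub.data.copy()))
            edges = conet.correlate_all_pairs(sub)
            net = conet.build_network(edges, r_min=config.r_min, q_max=config.q_max)
            if net.number_of_nodes() == 0:
                manifest.warnings.append(f"network for {label} is empty")
                continue
            partition, modularity = conet.partition_modules(net, seed=seeds[2])
            topo = conet.topology_summary(net, partition_modularity=modularity)
            ens = conet.random_ensemble_summary(
                net, n_draws=config.null_ensemble_size, seed=seeds[3]
            )
            row = topo.as_series()
            row["group"] = label
            for metric in ("avg_cc", "apd", "modularity"):
                key = {"avg_cc": "avg_cc", "apd": "apd", "modularity": "modularity"}[metric]
                row[f"random_{metric}_mean"] = ens.loc[key, "mean"]
                row[f"random_{metric}_sd"] = ens.loc[key, "sd"]
            topo_rows.append(row)
            roles = conet.node_roles(net, partition)
            roles.insert(0, "group", label)
            role_frames.append(roles)
        topo_frame = pd.DataFrame(topo_rows)
        p = outdir / "network_topology.tsv"
        topo_frame.to_csv(p, sep="\t", index=False)
        roles_frame = pd.concat(role_frames)
        p2 = outdir / "node_roles.tsv"
        roles_frame.to_csv(p2, sep="\t", index_label="node")
        report["network_topology"] = topo_frame
        report["node_roles"] = roles_frame
        manifest.record("conet", {"network_topology": p, "node_roles": p2})

    # -- importance ---------------------------------------------------------
    if functional is None:
        manifest.record("importance", {}, status="skipped", reason="no functional table")
    else:
        shared = [s for s in functional.samples if s in sample_score.index]
        X = functional.subset_samples(shared).values.T
        y, _ = discretize_target(sample_score.loc[shared].to_numpy(), n_bins=3)
        imp = mean_decrease_accuracy(
            X, y, feature_names=functional.features, repeats=5, seed=seeds[4], folds=5
        )
        frame = imp.frame()
        p = outdir / "importance.tsv"
        frame.to_csv(p, sep="\t", index_label="category")
        report["importance"] = frame
        report["importance_baseline_accuracy"] = imp.baseline_score
        manifest.record("importance", {"importance": p})

    manifest.write(outdir / "run_manifest.json")
    return manifest, report
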