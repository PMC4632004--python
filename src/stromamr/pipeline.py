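"""End-to-end pipeline: simulate -> subtype -> score -> network -> mra ->
survive, driven by one declarative YAML configuration.

Every stage writes its artifacts as TSV/GMT next to a manifest listing
(file, stage, sha256). Re-running with the same configuration reproduces
identical checksums for all deterministic artifacts. A stage failure aborts
the run with the failing stage named; artifacts already written are kept.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import enrichment, io, network, prognosis, simulate, subtypes
from .datatypes import GeneSet

logger = logging.getLogger(__name__)

DEFAULTS: dict = {
    "seed": None,
    "simulate": {f.name: f.default for f in
                 dataclasses.fields(simulate.CohortConfig)
                 if f.name != "seed"},
    "subtype": {
        "k": 4,
        "method": "kmeans",
        "n_reps": 20,
        "subsample_fraction": 0.8,
        "sam_permutations": 200,
        "sam_q": 0.05,
        "cv_folds": 5,
    },
    "score": {"alpha": 0.25},
    "network": {
        "n_permutations": 100,
        "bh_alpha": 0.05,
        "n_bootstraps": 30,
        "support_threshold": 0.6,
        "dpi_epsilon": 0.0,
        "min_regulon_size": 15,
        "mra_fdr": 0.05,
    },
    "survive": {"alpha": 0.25},
}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclasses.dataclass
class PipelineConfig:
    seed: int
    simulate: dict
    subtype: dict
    score: dict
    network: dict
    survive: dict

    def cohort_config(self) -> simulate.CohortConfig:
        cfg = simulate.CohortConfig(seed=self.seed, **{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in self.simulate.items()})
        cfg.validate()
        return cfg


def validate_config(path: str | Path | None = None,
                    overrides: dict | None = None) -> PipelineConfig:
    """Parse, default and cross-validate a pipeline configuration.

    Unknown keys raise an error naming the key. A missing seed is drawn
    from system entropy and logged so the run stays reproducible.
    """
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    if overrides:
        raw.update(overrides)
    merged: dict = {}
    for key, value in raw.items():
        if key not in DEFAULTS:
            raise PipelineError(f"unknown configuration key {key!r}")
        if isinstance(DEFAULTS[key], dict):
            block = dict(DEFAULTS[key])
            for sub, sub_value in (value or {}).items():
                if sub not in block:
                    raise PipelineError(
                        f"unknown configuration key {key}.{sub!r}")
                block[sub] = sub_value
            merged[key] = block
        else:
            merged[key] = value
    for key, default in DEFAULTS.items():
        merged.setdefault(key, dict(default)
                          if isinstance(default, dict) else default)
    if merged["seed"] is None:
        merged["seed"] = int(np.random.SeedSequence().entropy % (2 ** 31))
        logger.info("no seed configured; drew seed %d", merged["seed"])
    config = PipelineConfig(**merged)
    config.cohort_config()          # validate the simulate block up front
    logger.info("effective configuration: %s", dataclasses.asdict(config))
    return config


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Manifest:
    def __init__(self, outdir: Path):
        self.outdir = outdir
        self.rows: list[tuple[str, str, str]] = []

    def add(self, path: Path, stage: str) -> None:
        self.rows.append((path.name, stage, _sha256(path)))

    def write(self) -> Path:
        path = self.outdir / "manifest.tsv"
        pd.DataFrame(self.rows, columns=["file", "stage", "sha256"]).to_csv(
            path, sep="\t", index=False)
        return path


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> pd.DataFrame:
    """Execute every stage in order and return the artifact manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(outdir)
    with open(outdir / "effective_config.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh)
    manifest.add(outdir / "effective_config.yaml", "config")

    stage = "simulate"
    try:
        cohort = _stage_simulate(config, outdir, manifest)
        stage = "subtype"
        signature, labels = _stage_subtype(config, cohort, outdir, manifest)
        stage = "score"
        _stage_score(config, cohort, outdir, manifest)
        stage = "network"
        net = _stage_network(config, cohort, outdir, manifest)
        stage = "mra"
        _stage_mra(config, net, signature, outdir, manifest)
        stage = "survive"
        _stage_survive(config, cohort, outdir, manifest)
    except Exception as exc:
        manifest.write()
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    path = manifest.write()
    logger.info("pipeline complete; manifest at %s", path)
    return pd.read_csv(path, sep="\t")


def _timed(stage):
    start = time.perf_counter()
    return lambda: logger.info("stage %s finished in %.1f s", stage,
                               time.perf_counter() - start)


def _stage_simulate(config, outdir, manifest):
    done = _timed("simulate")
    cohort = simulate.generate_cohort(config.cohort_config())
    io.write_expression(cohort.expression, outdir / "expression.tsv")
    io.write_survival(cohort.survival, outdir / "survival.tsv")
    io.write_gmt([cohort.mese_signature, cohort.immu_signature,
                  cohort.mese_mrs, cohort.immu_mrs],
                 outdir / "planted_sets.gmt")
    truth = pd.DataFrame({"subtype": cohort.true_subtype,
                          "stromal_fraction": cohort.stromal_fraction})
    truth.to_csv(outdir / "truth.tsv", sep="\t", index_label="sample_id")
    for name in ("expression.tsv", "survival.tsv", "planted_sets.gmt",
                 "truth.tsv"):
        manifest.add(outdir / name, "simulate")
    done()
    return cohort


def _stage_subtype(config, cohort, outdir, manifest):
    done = _timed("subtype")
    p = config.subtype
    X = cohort.expression
    results = subtypes.consensus_cluster(
        X, [p["k"]], method=p["method"], n_reps=p["n_reps"],
        subsample_fraction=p["subsample_fraction"], seed=config.seed)
    res = results[0]
    res.consensus_matrix.to_csv(outdir / "consensus.tsv", sep="\t")
    core, widths = subtypes.silhouette_filter(
        1.0 - res.consensus_matrix.to_numpy(), res.labels)
    pd.DataFrame({"cluster": res.labels, "silhouette": widths,
                  "core": widths > 0}).to_csv(
        outdir / "labels.tsv", sep="\t", index_label="sample_id")
    core_X = X.subset_samples(core)
    core_labels = res.labels.loc[core]
    sam = subtypes.sam_multiclass(core_X, core_labels,
                                  n_permutations=p["sam_permutations"],
                                  seed=config.seed)
    selected = sam.index[sam["q"] < p["sam_q"]]
    signature = subtypes.pam_train(core_X.subset_genes(selected),
                                   core_labels, cv_folds=p["cv_folds"],
                                   seed=config.seed, sam_stats=sam)
    signature.cv_error_curve.to_csv(outdir / "cv_error.tsv", sep="\t",
                                    index=False)
    io.write_gmt(list(signature.up_sets.values()),
                 outdir / "subtype_signature.gmt")
    for name in ("consensus.tsv", "labels.tsv", "cv_error.tsv",
                 "subtype_signature.gmt"):
        manifest.add(outdir / name, "subtype")
    done()
    return signature, res.labels


def _stage_score(config, cohort, outdir, manifest):
    done = _timed("score")
    scores = enrichment.estimate_scores(
        cohort.expression, cohort.mese_signature, cohort.immu_signature,
        alpha=config.score["alpha"])
    scores.to_csv(outdir / "stromal_scores.tsv", sep="\t")
    manifest.add(outdir / "stromal_scores.tsv", "score")
    done()
    return scores


def _stage_network(config, cohort, outdir, manifest):
    done = _timed("network")
    p = config.network
    net = network.infer_regulons(
        cohort.expression, cohort.tf_list,
        n_permutations=p["n_permutations"], bh_alpha=p["bh_alpha"],
        seed=config.seed)
    net = network.bootstrap_filter(
        cohort.expression, net, n_bootstraps=p["n_bootstraps"],
        support_threshold=p["support_threshold"], seed=config.seed)
    net = network.apply_dpi(net, epsilon=p["dpi_epsilon"])
    io.write_network(net, outdir / "network.tsv")
    manifest.add(outdir / "network.tsv", "network")
    done()
    return net


def _stage_mra(config, net, signature, outdir, manifest):
    done = _timed("mra")
    p = config.network
    frames = []
    for cls, gene_set in signature.up_sets.items():
        try:
            result = network.mra(net, gene_set,
                                 min_regulon_size=p["min_regulon_size"],
                                 fdr=p["mra_fdr"])
        except network.NetworkError as exc:
            logger.warning("MRA skipped for cluster %s: %s", cls, exc)
            continue
        table = result.table.copy()
        table.insert(0, "cluster", str(cls))
        frames.append(table)
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    out.to_csv(outdir / "mra.tsv", sep="\t", index=False)
    manifest.add(outdir / "mra.tsv", "mra")
    done()
    return out


def _stage_survive(config, cohort, outdir, manifest):
    done = _timed("survive")
    table = prognosis.score_and_stratify(
        cohort.expression, cohort.mese_mrs, cohort.immu_mrs,
        alpha=config.survive["alpha"])
    surv = cohort.survival.aligned_to(cohort.expression.sample_ids)
    table = table.join(surv.set_index("sample_id")[["time", "event"]])
    table.to_csv(outdir / "prognostic_groups.tsv", sep="\t")
    chi2, p = prognosis.logrank_test(table["time"], table["event"],
                                     table["group"])
    rows = []
    for g, grp in table.groupby("group"):
        if grp["event"].sum() == 0:
            continue
        km = prognosis.km_estimate(grp["time"], grp["event"])
        km.insert(0, "group", g)
        rows.append(km.reset_index())
    pd.concat(rows, ignore_index=True).to_csv(outdir / "km_curves.tsv",
                                              sep="\t", index=False)
    pd.DataFrame({"statistic": ["logrank_chi2", "logrank_p"],
                  "value": [chi2, p]}).to_csv(
        outdir / "survival_tests.tsv", sep="\t", index=False)
    for name in ("prognostic_groups.tsv", "km_curves.tsv",
                 "survival_tests.tsv"):
        manifest.add(outdir / name, "survive")
    done()
    return table


def packaged_mr_signature() -> tuple[GeneSet, GeneSet]:
    """The shipped 16-gene master-regulator signature (6 + 10 symbols)."""
    path = Path(__file__).parent / "resources" / "mr_signature.gmt"
    sets = {gs.name: gs for gs in io.read_gmt(path)}
    return sets["MESENCHYMAL_MRS"], sets["IMMUNOREACTIVE_MRS"]
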