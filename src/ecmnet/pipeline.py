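"""End-to-end orchestration: cohort -> filter -> networks -> scores -> survival.

Plumbing only: each stage calls the corresponding analysis module, writes
its outputs under ``<out_dir>/<stage>/`` and records a manifest with
content hashes (sha256) of its inputs, parameters and outputs.  Reruns
skip stages whose input hashes and outputs are unchanged; a corrupted
intermediate file makes downstream stages refuse with a provenance error
instead of silently consuming it.  Given a fixed seed the full synthetic
run is bit-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import annotations, matrix_scores, networks, synthetic
from .cohort_io import (AbundanceMatrix, ClinicalTable, read_abundance, read_clinical,
                        read_gmt, write_abundance, write_clinical, write_gmt)

logger = logging.getLogger(__name__)

STAGES = ("cohort", "filter", "networks", "scores", "survival")


class ProvenanceError(RuntimeError):
    """An intermediate file does not match the hash its producing stage recorded."""


@dataclass
class RunConfig:
    out_dir: str
    seed: int = 0
    cohort: dict = field(default_factory=lambda: {"simulate": True})
    networks: dict = field(default_factory=dict)
    scores: dict = field(default_factory=dict)
    survival: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {"out_dir", "seed", "cohort", "networks", "scores", "survival"}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "out_dir" not in raw:
            raise ValueError("config must set out_dir")
        return cls(**raw)

    def validate(self):
        if not self.cohort.get("simulate", False):
            for key in ("matrix", "clinical"):
                path = self.cohort.get(key)
                if not path or not Path(path).exists():
                    raise FileNotFoundError(f"cohort.{key} file not found: {path}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _params_hash(params: dict) -> str:
    return hashlib.sha256(json.dumps(params, sort_keys=True, default=str).encode()).hexdigest()


class _Runner:
    def __init__(self, config: RunConfig):
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifests: dict[str, dict] = {}

    # -- manifest helpers ---------------------------------------------------

    def _manifest_path(self, stage: str) -> Path:
        return self.out / stage / "manifest.json"

    def _load_manifest(self, stage: str) -> dict | None:
        path = self._manifest_path(stage)
        if path.exists():
            with open(path) as fh:
                return json.load(fh)
        return None

    def _outputs_state(self, manifest: dict) -> str:
        """'intact', 'missing' (safe to rebuild) or 'corrupted' (tampered)."""
        state = "intact"
        for rel, digest in manifest["outputs"].items():
            target = self.out / rel
            if not target.exists():
                state = "missing"
            elif _sha256(target) != digest:
                return "corrupted"
        return state

    def _require(self, stage: str, rel: str) -> Path:
        """Fetch an upstream output, verifying it against its manifest."""
        manifest = self.manifests.get(stage) or self._load_manifest(stage)
        if manifest is None:
            raise ProvenanceError(f"stage {stage!r} has not produced a manifest")
        if rel not in manifest["outputs"]:
            raise ProvenanceError(f"stage {stage!r} did not record output {rel!r}")
        target = self.out / rel
        if not target.exists():
            raise ProvenanceError(f"missing intermediate {rel!r} from stage {stage!r}")
        if _sha256(target) != manifest["outputs"][rel]:
            raise ProvenanceError(
                f"intermediate {rel!r} does not match the hash recorded by stage {stage!r}"
            )
        return target

    def _run_stage(self, stage: str, params: dict, input_hashes: dict, builder) -> dict:
        stage_dir = self.out / stage
        stage_dir.mkdir(parents=True, exist_ok=True)
        key = {"params": _params_hash(params), "inputs": input_hashes}
        previous = self._load_manifest(stage)
        if previous and previous["key"] == key:
            state = self._outputs_state(previous)
            if state == "corrupted":
                raise ProvenanceError(
                    f"stage {stage!r} outputs do not match the hash recorded in its "
                    "manifest; refusing to reuse or overwrite a tampered intermediate"
                )
            if state == "intact":
                logger.info("stage %s unchanged; skipped", stage)
                self.manifests[stage] = previous
                return previous
        written = builder(stage_dir)
        manifest = {
            "stage": stage, "key": key, "seed": self.config.seed,
            "outputs": {str(p.relative_to(self.out)): _sha256(p) for p in written},
        }
        with open(self._manifest_path(stage), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        self.manifests[stage] = manifest
        return manifest

    # -- stages -------------------------------------------------------------

    def stage_cohort(self):
        cfg = self.config.cohort
        params = {**cfg, "seed": self.config.seed}
        input_hashes = {}
        if not cfg.get("simulate", False):
            for key in ("matrix", "clinical", "annotation", "genesets"):
                if cfg.get(key):
                    input_hashes[key] = _sha256(Path(cfg[key]))

        def build(stage_dir: Path):
            if cfg.get("simulate", False):
                spec = synthetic.SyntheticCohortSpec(seed=self.config.seed)
                if "n_samples" in cfg:
                    spec.n_samples = int(cfg["n_samples"])
                matrix, clinical, truth = synthetic.generate_cohort(spec)
                catalog = synthetic.synthetic_catalog(spec)
                genesets = synthetic.truth_genesets(
                    truth, n_decoys=int(cfg.get("n_decoys", 2)), seed=self.config.seed)
                cat_rows = pd.DataFrame(
                    [{"gene": r.gene_symbol, "division": r.division, "category": r.category}
                     for r in catalog.records])
                cat_rows.to_csv(stage_dir / "annotation.csv", index=False)
                write_gmt(genesets, stage_dir / "genesets.gmt")
            else:
                matrix = read_abundance(cfg["matrix"])
                clinical = read_clinical(cfg["clinical"])
                if cfg.get("annotation"):
                    db = annotations.load_annotation_db(cfg["annotation"])
                else:
                    db = annotations.load_packaged_catalog()
                pd.DataFrame(
                    [{"gene": r.gene_symbol, "division": r.division, "category": r.category}
                     for r in db.records]).to_csv(stage_dir / "annotation.csv", index=False)
                if cfg.get("genesets"):
                    write_gmt(read_gmt(cfg["genesets"]), stage_dir / "genesets.gmt")
                else:
                    ref = Path(__file__).parent / "data" / "ecm_genesets.gmt"
                    write_gmt(read_gmt(ref), stage_dir / "genesets.gmt")
            write_abundance(matrix, stage_dir / "matrix.tsv")
            write_clinical(clinical, stage_dir / "clinical.csv")
            return [stage_dir / "matrix.tsv", stage_dir / "clinical.csv",
                    stage_dir / "annotation.csv", stage_dir / "genesets.gmt"]

        return self._run_stage("cohort", params, input_hashes, build)

    def stage_filter(self):
        matrix_path = self._require("cohort", "cohort/matrix.tsv")
        annot_path = self._require("cohort", "cohort/annotation.csv")
        input_hashes = {"matrix": _sha256(matrix_path), "annotation": _sha256(annot_path)}

        def build(stage_dir: Path):
            matrix = read_abundance(matrix_path)
            db = annotations.load_annotation_db(annot_path)
            filtered = annotations.filter_matrix(matrix, db)
            coverage = annotations.coverage_stats(matrix, db)
            write_abundance(filtered, stage_dir / "filtered_matrix.tsv")
            coverage.to_csv(stage_dir / "coverage.tsv", sep="\t", index=False)
            return [stage_dir / "filtered_matrix.tsv", stage_dir / "coverage.tsv"]

        return self._run_stage("filter", {}, input_hashes, build)

    def stage_networks(self):
        cfg = {"k_min": 2, "k_max": 8, "n_resamples": 250, "subsample_fraction": 0.8,
               "min_pairs": 10, "sigclust_n_sim": 200, **self.config.networks}
        filtered_path = self._require("filter", "filter/filtered_matrix.tsv")
        input_hashes = {"filtered_matrix": _sha256(filtered_path)}

        def build(stage_dir: Path):
            matrix = read_abundance(filtered_path)
            sim = networks.correlation_similarity(matrix, min_pairs=cfg["min_pairs"])
            result = networks.consensus_cluster(
                sim, k_range=range(cfg["k_min"], cfg["k_max"] + 1),
                n_resamples=cfg["n_resamples"],
                subsample_fraction=cfg["subsample_fraction"], seed=self.config.seed)
            sig = networks.sigclust(matrix.data.T.fillna(matrix.data.T.mean()),
                                    n_sim=cfg["sigclust_n_sim"], seed=self.config.seed)
            scores = networks.cluster_median_scores(matrix, result.assignments)
            sim.values.to_csv(stage_dir / "similarity.tsv", sep="\t", na_rep="NA")
            result.assignments.to_csv(stage_dir / "assignments.tsv", sep="\t")
            scores.to_csv(stage_dir / "cluster_scores.tsv", sep="\t", na_rep="NA")
            with open(stage_dir / "clustering.json", "w") as fh:
                json.dump({"chosen_k": result.chosen_k,
                           "pac": {str(k): v for k, v in result.pac.items()},
                           "stable": result.stable,
                           "sigclust": sig,
                           "resample_log": result.resample_log},
                          fh, indent=2, sort_keys=True)
            return [stage_dir / "similarity.tsv", stage_dir / "assignments.tsv",
                    stage_dir / "cluster_scores.tsv", stage_dir / "clustering.json"]

        return self._run_stage("networks", cfg, input_hashes, build)

    def stage_scores(self):
        cfg = {"rule": "median", **self.config.scores}
        filtered_path = self._require("filter", "filter/filtered_matrix.tsv")
        gmt_path = self._require("cohort", "cohort/genesets.gmt")
        input_hashes = {"filtered_matrix": _sha256(filtered_path), "genesets": _sha256(gmt_path)}

        def build(stage_dir: Path):
            matrix = read_abundance(filtered_path)
            collection = read_gmt(gmt_path)
            if cfg["rule"] == "ssgsea":
                scores = matrix_scores.geneset_ssgsea_score(matrix, collection)
            else:
                scores = matrix_scores.geneset_median_score(matrix, collection)
            scores.to_csv(stage_dir / "geneset_scores.tsv", sep="\t", na_rep="NA")
            return [stage_dir / "geneset_scores.tsv"]

        return self._run_stage("scores", cfg, input_hashes, build)

    def stage_survival(self):
        cfg = {"endpoints": ["OS", "LRFS", "MFS"], "alpha": 0.05, "rule": "median",
               **self.config.survival}
        filtered_path = self._require("filter", "filter/filtered_matrix.tsv")
        clinical_path = self._require("cohort", "cohort/clinical.csv")
        gmt_path = self._require("cohort", "cohort/genesets.gmt")
        input_hashes = {"filtered_matrix": _sha256(filtered_path),
                        "clinical": _sha256(clinical_path), "genesets": _sha256(gmt_path)}

        def build(stage_dir: Path):
            matrix = read_abundance(filtered_path)
            clinical = read_clinical(clinical_path)
            collection = read_gmt(gmt_path)
            report = matrix_scores.prognostic_screen(
                matrix, collection, clinical, endpoints=tuple(cfg["endpoints"]),
                alpha=cfg["alpha"], score_rule=cfg["rule"])
            report.stage1.to_csv(stage_dir / "screen_stage1.tsv", sep="\t", index=False)
            mva_rows = []
            for name, per_ep in sorted(report.stage2.items()):
                for label, res in sorted(per_ep.items()):
                    row = res.table.loc["score_high"]
                    mva_rows.append({"gene_set": name, "endpoint": label,
                                     "hr": row["hr"], "hr_lower": row["hr_lower"],
                                     "hr_upper": row["hr_upper"], "p": row["p"]})
            pd.DataFrame(mva_rows).to_csv(stage_dir / "screen_mva.tsv", sep="\t", index=False)
            with open(stage_dir / "screen.json", "w") as fh:
                json.dump({"retained": report.retained, "config": report.config},
                          fh, indent=2, sort_keys=True)
            return [stage_dir / "screen_stage1.tsv", stage_dir / "screen_mva.tsv",
                    stage_dir / "screen.json"]

        return self._run_stage("survival", cfg, input_hashes, build)


def run_full_analysis(config: RunConfig) -> dict:
    """Execute all stages in dependency order and write a run summary.

    A stage failure halts downstream stages but preserves completed
    upstream outputs.  Returns the summary dict (also written to
    ``<out_dir>/run_summary.json``).
    """
    config.validate()
    runner = _Runner(config)
    summary = {"seed": config.seed, "stages": {}}
    try:
        for stage in STAGES:
            manifest = getattr(runner, f"stage_{stage}")()
            summary["stages"][stage] = manifest
    finally:
        with open(Path(config.out_dir) / "run_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
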