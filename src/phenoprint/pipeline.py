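"""End-to-end orchestration: simulate -> encode -> blur -> cluster ->
fingerprints -> outcomes, with reproducibility metadata.

A run is described by a :class:`RunConfig` (typically loaded from a
YAML file).  :func:`run_pipeline` executes the stages in order, writes
every intermediate artifact as delimited text under the output
directory, and emits a manifest (config echo, seed, per-stage counts,
SHA-256 checksums of outputs).  Rerunning an identical config
reproduces identical checksums.

A single global seed is fanned out to per-stage substreams by fixed
offsets so that each stage is individually reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, encoding, outcomes, synthetic
from .blur import blur_stack
from .registry import default_registry, load_registry

__all__ = ["RunConfig", "run_pipeline"]

# fixed per-stage seed offsets fanned out from the global seed
_STAGE_SEED_OFFSET = {"simulate": 0, "cluster": 1}


@dataclass
class RunConfig:
    """Validated configuration of a pipeline run."""

    outdir: str
    seed: int = 0
    # input tables; left empty when simulating
    patients_path: str | None = None
    events_path: str | None = None
    outcomes_path: str | None = None
    registry_path: str | None = None
    # synthetic-cohort stage (used when no input tables are given)
    simulate: bool = False
    n_per_archetype: int = 100
    separation: float = 1.0
    # blurring
    half_window: int = 10
    decay: float = 10.0
    # clustering: either a fixed k, or a scan range (k written as None)
    k: int | None = None
    k_min: int = 2
    k_max: int = 20
    n_restarts: int = 10
    # outcomes
    reference_label: int | None = None

    def validate(self) -> None:
        if self.k is None and self.k_min > self.k_max:
            raise ValueError("k_min must be <= k_max")
        if not self.simulate and (self.patients_path is None or self.events_path is None):
            raise ValueError("need patients/events tables unless simulate=true")
        if self.half_window < 0 or self.decay <= 0:
            raise ValueError("half_window must be >= 0 and decay > 0")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        cfg = cls(**doc)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run all configured stages and return the manifest dict."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    registry = (
        load_registry(config.registry_path, allow_incomplete=True)
        if config.registry_path
        else default_registry()
    )
    manifest: dict = {
        "config": config.to_dict(),
        "seed": config.seed,
        "stages": {},
        "outputs": {},
    }

    # --- stage: inputs ----------------------------------------------------
    if config.simulate:
        specs = synthetic.default_archetypes(config.n_per_archetype, config.separation)
        cohort = synthetic.generate(
            specs, seed=config.seed + _STAGE_SEED_OFFSET["simulate"], registry=registry
        )
        patients, events, outcome_records = cohort.patients, cohort.events, cohort.outcomes
        labels_df = pd.DataFrame(
            sorted(cohort.true_labels.items()), columns=["patient_id", "archetype"]
        )
        _write_tsv(outdir / "patients.tsv", patients)
        _write_tsv(outdir / "events.tsv", events)
        _write_tsv(outdir / "outcomes.tsv", outcome_records)
        _write_tsv(outdir / "true_labels.tsv", labels_df)
        manifest["stages"]["simulate"] = {
            "n_patients": len(patients),
            "n_events": len(events),
        }
    else:
        patients = pd.read_csv(config.patients_path, sep="\t", dtype={"patient_id": str})
        events = pd.read_csv(config.events_path, sep="\t", dtype={"patient_id": str, "code": str})
        outcome_records = (
            pd.read_csv(config.outcomes_path, sep="\t", dtype={"patient_id": str})
            if config.outcomes_path
            else None
        )
        manifest["stages"]["load"] = {
            "n_patients": len(patients),
            "n_events": len(events),
        }

    # --- stage: encode ----------------------------------------------------
    stack = encoding.encode_cohort(events, registry, patients=patients)
    encoding.write_images(outdir / "images.tsv", stack)
    manifest["stages"]["encode"] = {
        "n_images": len(stack),
        "shape": list(stack.array.shape[1:]),
    }

    # --- stage: blur ------------------------------------------------------
    blurred = blur_stack(stack, config.half_window, config.decay)
    encoding.write_images(outdir / "blurred.tsv", blurred)
    manifest["stages"]["blur"] = {"n_images": len(blurred)}

    # --- stage: cluster (fixed k) or sse-scan -----------------------------
    cluster_seed = config.seed + _STAGE_SEED_OFFSET["cluster"]
    if config.k is None:
        curve = clustering.sse_scan(
            blurred, config.k_min, config.k_max, seed=cluster_seed, n_restarts=config.n_restarts
        )
        sse_df = pd.DataFrame(curve.points, columns=["k", "sse"])
        _write_tsv(outdir / "sse_curve.tsv", sse_df)
        lo, hi = clustering.suggest_elbow(curve)
        manifest["stages"]["sse_scan"] = {
            "n_points": len(curve.points),
            "elbow_area": [lo, hi],
        }
        model = None
    else:
        model = clustering.kmeans_fit(
            blurred, config.k, seed=cluster_seed, n_restarts=config.n_restarts
        )
        assign_df = pd.DataFrame(
            {"patient_id": model.patient_ids, "cluster": model.labels}
        )
        _write_tsv(outdir / "assignments.tsv", assign_df)
        manifest["stages"]["cluster"] = {"k": model.k, "sse": model.sse}

        # --- stage: fingerprints -----------------------------------------
        prints = clustering.fingerprints(stack, model)
        fp_stack = encoding.ImageStack(
            [f"cluster-{fp.cluster_label}" for fp in prints],
            np.stack([fp.mean_image for fp in prints]),
        )
        encoding.write_images(outdir / "fingerprints.tsv", fp_stack)
        manifest["stages"]["fingerprints"] = {
            "n_clusters": len(prints),
            "sizes": {fp.cluster_label: fp.n_patients for fp in prints},
        }

        # --- stage: outcomes ---------------------------------------------
        if outcome_records is not None:
            summaries = outcomes.summarize_outcomes(outcome_records, model.assignments)
            asd_table, test_table = outcomes.compare_clusters(
                summaries,
                outcome_records,
                model.assignments,
                reference_label=config.reference_label,
            )
            _write_tsv(outdir / "outcome_summary.tsv", summaries)
            _write_tsv(outdir / "outcome_asd.tsv", asd_table)
            _write_tsv(outdir / "outcome_tests.tsv", test_table)
            manifest["stages"]["outcomes"] = {
                "n_clusters": len(summaries),
                "n_asd_rows": len(asd_table),
            }

    # --- manifest ---------------------------------------------------------
    for p in sorted(outdir.iterdir()):
        if p.name != "manifest.json" and p.is_file():
            manifest["outputs"][p.name] = _sha256(p)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _write_tsv(path: Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)
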