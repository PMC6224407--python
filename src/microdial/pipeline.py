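"""End-to-end orchestration: load -> pool -> fingerprints -> analyses.

:func:`run_all` executes every stage with a single configuration, writes each
stage's TSV outputs plus a machine-readable ``manifest.json`` (stage
parameters, input content hashes, output row counts — no timestamps, so
identical inputs and seed yield byte-identical manifests) and logs progress.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import frequency, io, meta, mi, similarity, targets
from .fingerprints import (
    build_activity_matrix,
    chemical_fingerprint_frame,
    fingerprint_long,
    response_fingerprint,
    sign_census,
)
from .synth import SimConfig, generate_all, write_inputs

log = logging.getLogger("microdial.pipeline")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    outdir: str | Path = "microdial_run"
    # file inputs (ignored in synth mode)
    records: str | None = None
    annotations: str | None = None
    ontology: str | None = None
    predictions: str | None = None
    brain_targets: str | None = None
    # or generate everything
    synth: SimConfig | None = None
    # analysis parameters
    level: str = "coarse"
    granularity: str = "compound"
    metric: str = "jaccard_updown"
    min_class_size: int = 4
    completeness_min: float = 0.5
    impute_value: float = 100.0
    assoc_by: str = "neurochemical"
    assoc_mode: str = "category"
    hit_min: float = 100.0
    min_categories: int = 3
    mi_top_k: int = 5
    seed: int = 0

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        synth_cfg = raw.pop("synth", None)
        cfg = cls(**raw)
        if synth_cfg is not None:
            for key in ("replicates_per_tuple", "n_animals_range", "doses"):
                if key in synth_cfg:
                    synth_cfg[key] = tuple(synth_cfg[key])
            cfg.synth = SimConfig(**synth_cfg)
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> dict:
    df.to_csv(path, sep="\t", index=index)
    return {"path": path.name, "sha256": _sha256(path), "rows": int(len(df))}


def run_all(cfg: PipelineConfig) -> dict:
    """Run every stage; returns the manifest (also written as manifest.json)."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "stages": []}

    def stage(name: str, fn):
        log.info("stage %s", name)
        try:
            outputs, params = fn()
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(name, exc) from exc
        manifest["stages"].append({"stage": name, "params": params, "outputs": outputs})

    state: dict = {}

    def s_load():
        if cfg.synth is not None:
            bundle = generate_all(cfg.synth)
            paths = write_inputs(bundle, outdir / "inputs")
            state["bundle"] = bundle
            rec, ann, ont = paths["records"], paths["annotations"], paths["ontology"]
            state["predictions_path"] = paths["predictions"]
            state["brain_targets_path"] = paths["brain_targets"]
        else:
            if cfg.records is None:
                raise ValueError("no records path and synth mode disabled")
            rec, ann, ont = cfg.records, cfg.annotations, cfg.ontology
            state["predictions_path"] = cfg.predictions
            state["brain_targets_path"] = cfg.brain_targets
        ds = io.read_dataset(rec, ann, ont)
        state["dataset"] = io.map_regions(ds, level=cfg.level) if ds.ontology else ds
        inputs = {
            "records": _sha256(Path(rec)),
            "annotations": _sha256(Path(ann)) if ann else None,
            "ontology": _sha256(Path(ont)) if ont else None,
        }
        summary = io.summarize_dataset(state["dataset"])
        rows = []
        for table, df in summary.items():
            for cat, r in df.iterrows():
                rows.append({"table": table, "category": cat, "n": int(r["n"]),
                             "pct": r["pct"]})
        out = _write(pd.DataFrame(rows), outdir / "summary.tsv")
        out2 = {
            "completeness": io.completeness(state["dataset"]),
            "inputs": inputs,
        }
        return [out], {"level": cfg.level} | out2

    def s_pool():
        pooled = meta.pool_dataset(state["dataset"])
        state["pooled"] = pooled
        return [_write(pooled, outdir / "pooled.tsv")], {}

    def s_fingerprints():
        activity = build_activity_matrix(state["pooled"], granularity=cfg.granularity)
        fps = response_fingerprint(activity)
        state["activity"], state["fps"] = activity, fps
        long = fingerprint_long(fps)
        act_long = activity.stack(["brain_region", "neurochemical"], future_stack=True)
        act_long = act_long.dropna().rename("activity_pct").reset_index()
        outs = [
            _write(long, outdir / "fingerprints.tsv"),
            _write(act_long, outdir / "activity.tsv"),
        ]
        return outs, {"granularity": cfg.granularity, "census": sign_census(fps)}

    def s_similarity():
        ds = state["dataset"]
        chem = None
        if ds.annotations["smiles"].astype(bool).any():
            chem = chemical_fingerprint_frame(ds.annotations)
        res = similarity.intra_inter_atc(
            state["fps"], ds.annotations, space="response",
            metric=cfg.metric, min_class_size=cfg.min_class_size,
        )
        d_stat, p = similarity.ks_two_sample(res.intra.values, res.inter.values)
        summaries = [res.intra.summary(), res.inter.summary()]
        pairs = [res.pairs]
        if chem is not None:
            cres = similarity.intra_inter_atc(
                None, ds.annotations, space="chemical", chem=chem,
                min_class_size=cfg.min_class_size,
            )
            summaries += [cres.intra.summary(), cres.inter.summary()]
            pairs.append(cres.pairs)
        outs = [
            _write(pd.concat(pairs, ignore_index=True), outdir / "similarity.tsv"),
            _write(pd.DataFrame(summaries), outdir / "similarity_summary.tsv"),
        ]
        state["intra_inter"] = res
        return outs, {
            "metric": cfg.metric,
            "ks_D": d_stat,
            "ks_p": p,
            "n_undefined_pairs": res.n_undefined,
        }

    def s_frequency():
        freq = frequency.updown_fractions(state["fps"])
        outs = [_write(freq, outdir / "frequency.tsv")]
        try:
            clus = frequency.hierarchical_cluster(
                state["activity"], completeness_min=cfg.completeness_min,
                impute_value=cfg.impute_value,
            )
        except ValueError:
            return outs, {"clustered": False}
        outs.append(_write(
            frequency.linkage_table(clus.row_linkage, list(clus.matrix.index)),
            outdir / "linkage_rows.tsv",
        ))
        ordered = clus.matrix.loc[clus.row_order, clus.col_order]
        ordered.columns = [f"{r}|{n}" for r, n in ordered.columns]
        outs.append(_write(ordered.reset_index(), outdir / "clustered_matrix.tsv"))
        return outs, {
            "clustered": True,
            "completeness_min": cfg.completeness_min,
            "impute_value": cfg.impute_value,
            "n_dropped_rows": len(clus.dropped_rows),
        }

    def s_targets():
        path = state.get("predictions_path")
        if path is None:
            raise ValueError("no predictions path configured")
        tp = targets.read_predictions(path)
        params: dict = {}
        brain = state.get("brain_targets_path")
        if brain is not None:
            filt = targets.filter_brain_targets(tp, io.read_target_list(brain))
            tp = filt.matrix
            params["brain_targets_retained"] = filt.n_retained
            params["brain_targets_total"] = filt.n_total
        assoc = targets.hit_percentages(
            tp, state["fps"], by=cfg.assoc_by, mode=cfg.assoc_mode
        )
        links = targets.top_links(assoc, hit_min=cfg.hit_min,
                                  min_categories=cfg.min_categories)
        state["tp"], state["assoc"] = tp, assoc
        outs = [
            _write(targets.association_long(assoc), outdir / "association.tsv"),
            _write(links.links, outdir / "links.tsv"),
        ]
        return outs, params | {"by": cfg.assoc_by, "mode": cfg.assoc_mode,
                               "display_targets": links.display_targets}

    def s_mi():
        ds = state["dataset"]
        fps = state["fps"]
        outs, params = [], {}
        for space, ann in (
            ("atc", mi.atc_annotation_matrix(ds.annotations)),
            ("targets", state["tp"].astype(np.uint8) if "tp" in state else None),
        ):
            if ann is None:
                continue
            scores = mi.pairwise_nmi_matrix(ann, fps)
            overall = mi.aggregate_mi(scores, per="overall")
            top = mi.top_k_features(scores, k=cfg.mi_top_k)
            robust = mi.loo_mi_robustness(ann, fps, scores=scores)
            outs.append(_write(scores, outdir / f"mi_scores_{space}.tsv"))
            outs.append(_write(top, outdir / f"mi_top_{space}.tsv"))
            params[space] = {
                "median": overall.median,
                "sd": overall.sd,
                "n_labels": overall.n_labels,
                "loo_sd": robust.sd,
            }
        return outs, params

    stage("load", s_load)
    stage("meta", s_pool)
    stage("fingerprints", s_fingerprints)
    stage("similarity", s_similarity)
    stage("frequency", s_frequency)
    stage("targets", s_targets)
    stage("mutual_information", s_mi)

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return manifest
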