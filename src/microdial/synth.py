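"""Synthetic microdialysis datasets with planted, parameterized structure.

The generator emulates the statistical shape of a curated microdialysis
study-record collection so every pipeline stage is testable without any
external download:

* drugs fall into ATC-like classes; each class has a ternary *prototype*
  response pattern over a (coarse region x transmitter) grid, with
  transmitter-level sparsity (a class modulates only a subset of
  transmitters);
* each drug inherits its class prototype with independent per-tuple sign
  flips at rate ``flip_prob`` — the planted class coherence that the
  similarity analyses should recover;
* each measured tuple (kept with probability ``completeness``) produces a
  handful of replicate study records whose peak percent-of-baseline effects
  are drawn log-normally around a sign-specific mean (multiplicative noise,
  respecting positivity of percent-of-baseline data), with animal counts and
  covariates sampled to mirror the heavy male / adult / freely-moving skew of
  the literature;
* *driver* protein targets are planted per transmitter: a drug that truly
  modulates a transmitter is predicted active at that transmitter's drivers
  with probability ``p_active_driver`` (pi1) versus background
  ``p_active_background`` (pi0) — the planted signal for the target
  association and mutual-information analyses;
* each class gets a chemical scaffold; members are the scaffold with distinct
  substituents, so intra-class chemical similarity exceeds inter-class.

All randomness flows from ``SimConfig.seed`` through named substreams
(dataset / predictions / smiles), so each component is independently
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import RECORD_COLUMNS, Dataset, write_dataset

_SUBSTREAM = {"dataset": 0, "predictions": 1, "smiles": 2}

_SCAFFOLDS = [
    "c1ccccc1",          # benzene
    "c1ccncc1",          # pyridine
    "c1ccc2ccccc2c1",    # naphthalene
    "C1CCCCC1",          # cyclohexane
    "c1ccoc1",           # furan
    "c1ccsc1",           # thiophene
    "c1cc[nH]c1",        # pyrrole
    "c1ccc2[nH]ccc2c1",  # indole
    "C1CCNCC1",          # piperidine
    "c1cnccn1",          # pyrazine
    "C1CCOC1",           # tetrahydrofuran
    "c1ccc2ncccc2c1",    # quinoline
]

_DECORATIONS = [
    "C", "CC", "CCC", "CCCC", "CCCCC", "OC", "OCC", "OCCC", "NC", "NCC",
    "NCCC", "ClC", "FC", "BrC", "COC", "CCOC", "C(C)C", "CC(C)C", "OCCO", "CNC",
]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the synthetic benchmark.

    Defaults are the conditions used throughout the package's recovery
    analyses: 6 classes x 5 drugs on an 8 x 8 region-by-transmitter grid,
    70% tuple completeness, 10% sign-flip noise, log-normal effect noise of
    0.1 on the log scale around 160% (up) / 70% (down) of baseline, and a
    16-target prediction space with one planted driver per transmitter
    (pi1 = 0.9, pi0 = 0.1).
    """

    n_classes: int = 6
    drugs_per_class: int = 5
    n_regions: int = 8
    n_transmitters: int = 8
    completeness: float = 0.7
    flip_prob: float = 0.1
    replicates_per_tuple: tuple[int, int] = (2, 4)
    n_animals_range: tuple[int, int] = (4, 12)
    effect_up_mean: float = 160.0
    effect_down_mean: float = 70.0
    effect_sd_log: float = 0.1
    n_targets: int = 16
    n_decoy_targets: int = 4
    drivers_per_transmitter: int = 1
    p_active_driver: float = 0.9      # pi1
    p_active_background: float = 0.1  # pi0
    p_transmitter_modulated: float = 0.5
    p_up: float = 0.57
    p_zero: float = 0.0
    p_male: float = 0.96
    subregions_per_region: int = 1
    atc_coverage: float = 1.0
    doses: tuple[float, ...] = (10.0,)
    monoamine_bias: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_regions < 1 or self.n_transmitters < 1:
            raise ValueError("degenerate grid: need at least 1 region and 1 transmitter")
        if not (0.0 < self.completeness <= 1.0):
            raise ValueError("completeness must lie in (0, 1]")
        if not (0.0 <= self.flip_prob <= 0.5):
            raise ValueError("flip_prob must lie in [0, 0.5]")
        if self.p_active_driver < self.p_active_background:
            raise ValueError("pi1 must be >= pi0")
        if not (self.effect_up_mean > 100.0 > self.effect_down_mean > 0.0):
            raise ValueError("need effect_up_mean > 100 > effect_down_mean > 0")

    def rng(self, substream: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _SUBSTREAM[substream]])


@dataclass
class PlantedTruth:
    """Ground truth behind a generated dataset."""

    drugs: list[str]
    class_of: dict[str, str]          # drug -> ATC-like class code
    prototypes: pd.DataFrame          # class x (region, transmitter) signs
    drug_signs: pd.DataFrame          # drug x (region, transmitter) signs (post-flip)
    transmitters: list[str]
    regions: list[str]

    def modulates(self) -> pd.DataFrame:
        """Boolean drug x transmitter: any non-zero sign at that transmitter."""
        by_t = self.drug_signs.ne(0).T.groupby(level="neurochemical").any().T
        return by_t[self.transmitters]


def _tuple_index(regions, transmitters) -> pd.MultiIndex:
    return pd.MultiIndex.from_product(
        [regions, transmitters], names=["brain_region", "neurochemical"]
    )


def generate_dataset(cfg: SimConfig) -> tuple[Dataset, PlantedTruth]:
    """Generate study records, annotations and ontology with planted classes."""
    rng = cfg.rng("dataset")
    regions = [f"region{i:02d}" for i in range(cfg.n_regions)]
    transmitters = [f"nt{i:02d}" for i in range(cfg.n_transmitters)]
    cols = _tuple_index(regions, transmitters)
    class_codes = [f"N{i + 1:02d}A" for i in range(cfg.n_classes)]
    drugs = [f"drug{i:03d}" for i in range(cfg.n_classes * cfg.drugs_per_class)]
    class_of = {d: class_codes[i // cfg.drugs_per_class] for i, d in enumerate(drugs)}

    # class prototypes: transmitter-level activity, then per-tuple signs
    n_t = len(transmitters)
    modulated = rng.random((cfg.n_classes, n_t)) < cfg.p_transmitter_modulated
    # every class modulates at least one transmitter
    for c in range(cfg.n_classes):
        if not modulated[c].any():
            modulated[c, rng.integers(n_t)] = True
    proto = np.zeros((cfg.n_classes, len(cols)), dtype=np.int8)
    t_of_col = np.array([transmitters.index(t) for _, t in cols])
    for c in range(cfg.n_classes):
        active_cols = modulated[c, t_of_col]
        signs = np.where(rng.random(len(cols)) < cfg.p_up, 1, -1).astype(np.int8)
        if cfg.p_zero > 0:
            signs[rng.random(len(cols)) < cfg.p_zero] = 0
        proto[c] = np.where(active_cols, signs, 0)
    prototypes = pd.DataFrame(proto, index=pd.Index(class_codes, name="class"), columns=cols)

    # drugs inherit prototypes with per-tuple flips
    class_idx = np.array([class_codes.index(class_of[d]) for d in drugs])
    signs = proto[class_idx].copy()
    flip = rng.random(signs.shape) < cfg.flip_prob
    new_signs = np.where(rng.random(signs.shape) < cfg.p_up, 1, -1).astype(np.int8)
    signs = np.where(flip, np.where(signs != 0, -signs, new_signs), signs)
    drug_signs = pd.DataFrame(signs, index=pd.Index(drugs, name="compound"), columns=cols)

    # missingness: MCAR, optionally biased toward the first transmitters
    p_measure = np.full(len(cols), cfg.completeness)
    if cfg.monoamine_bias is not None:
        favoured = t_of_col < max(1, n_t // 4)
        p_measure = np.where(
            favoured,
            np.minimum(1.0, cfg.completeness * cfg.monoamine_bias),
            cfg.completeness / cfg.monoamine_bias,
        )
    measured = rng.random(signs.shape) < p_measure

    # expand measured (drug, tuple, dose) conditions into replicate records
    d_idx, c_idx = np.nonzero(measured)
    n_cond = len(d_idx)
    peak_times = rng.choice([20.0, 40.0, 60.0, 80.0, 100.0, 120.0], size=n_cond)
    lo, hi = cfg.replicates_per_tuple
    frames = []
    for dose in cfg.doses:
        reps = rng.integers(lo, hi + 1, size=n_cond)
        rd = np.repeat(d_idx, reps)
        rc = np.repeat(c_idx, reps)
        rt = np.repeat(peak_times, reps)
        s = signs[rd, rc]
        n_rows = len(rd)
        z = rng.standard_normal(n_rows)
        x = np.where(
            s == 1,
            cfg.effect_up_mean * np.exp(cfg.effect_sd_log * z),
            np.where(
                s == -1,
                cfg.effect_down_mean * np.exp(cfg.effect_sd_log * z),
                100.0,
            ),
        )
        region_names = np.array(cols.get_level_values("brain_region"))[rc]
        if cfg.subregions_per_region > 1:
            sub = rng.integers(cfg.subregions_per_region, size=n_rows)
            region_names = np.array(
                [f"{r}_{chr(97 + s_)}" for r, s_ in zip(region_names, sub)]
            )
        anesthetized = rng.random(n_rows) >= 0.89
        frames.append(pd.DataFrame({
            "pmid": [f"{90000000 + i}" for i in range(n_rows)],
            "n_animals": rng.integers(
                cfg.n_animals_range[0], cfg.n_animals_range[1] + 1, size=n_rows
            ),
            "strain": rng.choice(
                ["sprague-dawley", "wistar", "long-evans"], p=[0.6, 0.3, 0.1], size=n_rows
            ),
            "sex": rng.choice(["male", "female"], p=[cfg.p_male, 1 - cfg.p_male], size=n_rows),
            "age_class": rng.choice(["adult", "adolescent", "aged"], p=[0.8, 0.15, 0.05], size=n_rows),
            "consciousness": np.where(anesthetized, "anesthetized", "freely_moving"),
            "anesthetic": np.where(anesthetized, "isoflurane", ""),
            "anesthetic_dose": np.where(anesthetized, 2.0, np.nan),
            "perfusate": rng.choice(["acsf", "ringer"], p=[0.7, 0.3], size=n_rows),
            "calcium_mM": rng.choice([1.2, 2.4], size=n_rows),
            "flow_rate": rng.choice([1.0, 1.5, 2.0], size=n_rows),
            "brain_region": region_names,
            "neurochemical": np.array(cols.get_level_values("neurochemical"))[rc],
            "drug": np.array(drugs)[rd],
            "dose": dose,
            "route": "ip",
            "peak_time": rt,
            "peak_pct_baseline": x,
        }))
    records = pd.concat(frames, ignore_index=True)[RECORD_COLUMNS]
    records["pmid"] = [f"{90000000 + i}" for i in range(len(records))]

    covered = rng.random(len(drugs)) < cfg.atc_coverage
    annotations = pd.DataFrame(
        {
            "smiles": [""] * len(drugs),
            "atc_codes": [
                frozenset([class_of[d]]) if cov else frozenset()
                for d, cov in zip(drugs, covered)
            ],
        },
        index=pd.Index(drugs, name="compound"),
    )
    if cfg.subregions_per_region > 1:
        ontology = {
            f"{r}_{chr(97 + s_)}": r
            for r in regions
            for s_ in range(cfg.subregions_per_region)
        }
    else:
        ontology = {r: r for r in regions}
    truth = PlantedTruth(
        drugs=drugs,
        class_of=class_of,
        prototypes=prototypes,
        drug_signs=drug_signs,
        transmitters=transmitters,
        regions=regions,
    )
    return Dataset(records=records, annotations=annotations, ontology=ontology), truth


@dataclass
class PredictionSet:
    """Planted target-prediction matrix.

    ``matrix`` covers the brain-expressed core targets plus a few decoy
    (non-brain) targets that the brain filter should remove; ``drivers`` maps
    each transmitter to its planted driver target(s); ``brain_targets`` is the
    companion brain-expressed gene list.
    """

    matrix: pd.DataFrame
    drivers: dict[str, list[str]]
    brain_targets: list[str]

    @property
    def driver_targets(self) -> set[str]:
        return {g for gs in self.drivers.values() for g in gs}


def generate_predictions(cfg: SimConfig, truth: PlantedTruth) -> PredictionSet:
    """Generate the binary drug x target matrix with planted drivers."""
    need = cfg.drivers_per_transmitter * len(truth.transmitters)
    if need > cfg.n_targets:
        raise ValueError(
            "drivers_per_transmitter x n_transmitters exceeds n_targets "
            f"({need} > {cfg.n_targets})"
        )
    rng = cfg.rng("predictions")
    core = [f"T{i:03d}" for i in range(cfg.n_targets)]
    decoys = [f"X{i:03d}" for i in range(cfg.n_decoy_targets)]
    order = rng.permutation(cfg.n_targets)
    drivers = {
        t: [core[order[i * cfg.drivers_per_transmitter + j]]
            for j in range(cfg.drivers_per_transmitter)]
        for i, t in enumerate(truth.transmitters)
    }
    modulates = truth.modulates().loc[truth.drugs]
    n_drugs = len(truth.drugs)
    all_targets = core + decoys
    mat = (rng.random((n_drugs, len(all_targets))) <
           cfg.p_active_background).astype(np.uint8)
    col_of = {g: i for i, g in enumerate(all_targets)}
    for t, genes in drivers.items():
        mod = modulates[t].to_numpy()
        p = np.where(mod, cfg.p_active_driver, cfg.p_active_background)
        for g in genes:
            mat[:, col_of[g]] = (rng.random(n_drugs) < p).astype(np.uint8)
    matrix = pd.DataFrame(
        mat, index=pd.Index(truth.drugs, name="compound"), columns=all_targets
    )
    return PredictionSet(matrix=matrix, drivers=drivers, brain_targets=core)


def generate_smiles(cfg: SimConfig) -> dict[str, str]:
    """Class-coherent toy SMILES: shared scaffold per class, distinct substituents."""
    from rdkit import Chem  # deferred: only needed when structures are requested

    if cfg.n_classes > len(_SCAFFOLDS):
        raise ValueError(f"at most {len(_SCAFFOLDS)} classes supported for SMILES generation")
    if cfg.drugs_per_class > len(_DECORATIONS):
        raise ValueError(
            f"more drugs per class than available decorations ({len(_DECORATIONS)})"
        )
    rng = cfg.rng("smiles")
    scaffold_idx = rng.choice(len(_SCAFFOLDS), size=cfg.n_classes, replace=False)
    out: dict[str, str] = {}
    i = 0
    for c in range(cfg.n_classes):
        scaffold = _SCAFFOLDS[scaffold_idx[c]]
        deco_idx = rng.choice(len(_DECORATIONS), size=cfg.drugs_per_class, replace=False)
        for j in range(cfg.drugs_per_class):
            smi = _DECORATIONS[deco_idx[j]] + scaffold
            if Chem.MolFromSmiles(smi) is None:  # pragma: no cover - guards the toy lists
                raise ValueError(f"generated SMILES failed to parse: {smi}")
            out[f"drug{i:03d}"] = smi
            i += 1
    return out


@dataclass
class SynthBundle:
    dataset: Dataset
    truth: PlantedTruth
    predictions: PredictionSet
    smiles: dict[str, str] = field(default_factory=dict)


def generate_all(cfg: SimConfig, with_smiles: bool = True) -> SynthBundle:
    """Generate dataset, predictions and (optionally) SMILES in one bundle."""
    ds, truth = generate_dataset(cfg)
    preds = generate_predictions(cfg, truth)
    smiles = generate_smiles(cfg) if with_smiles else {}
    if smiles:
        ann = ds.annotations.copy()
        ann["smiles"] = [smiles.get(d, "") for d in ann.index]
        ds = replace(ds, annotations=ann)
    return SynthBundle(dataset=ds, truth=truth, predictions=preds, smiles=smiles)


def write_inputs(bundle: SynthBundle, outdir: str | Path) -> dict[str, Path]:
    """Write the bundle in the exact file formats the readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = write_dataset(bundle.dataset, outdir)
    pred_path = outdir / "predictions.csv"
    bundle.predictions.matrix.to_csv(pred_path)
    brain_path = outdir / "brain_targets.txt"
    brain_path.write_text("\n".join(bundle.predictions.brain_targets) + "\n")
    paths |= {"predictions": pred_path, "brain_targets": brain_path}
    return paths
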