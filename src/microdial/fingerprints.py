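"""Ternary neurochemical response fingerprints and hashed chemical fingerprints.

The *activity* of a compound at a (brain region, neurochemical) tuple is the
minimum pooled response across all its doses and peak times (the arithmetic
minimum of percent-of-baseline values, so strong decreases dominate; an
alternative maximum-|deviation-from-baseline| rule is available for
sensitivity checks). Activities are then ternarised against the 100% baseline
into sparse response fingerprints:

    +1  response increased above 100% of baseline
    -1  response decreased below 100%
     0  response exactly at baseline ("no change")
    NaN tuple never measured for that compound

Chemical structure is encoded as hashed circular (Morgan) fingerprints with
radius 2 folded to 2048 bits, computed with RDKit on the desalted,
stereo-stripped canonical form of the input SMILES.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

#: MultiIndex column level names of activity / fingerprint matrices.
TUPLE_LEVELS = ("brain_region", "neurochemical")


def build_activity_matrix(
    pooled: pd.DataFrame,
    granularity: str = "compound",
    rule: str = "min",
) -> pd.DataFrame:
    """Collapse pooled effects into a compound x (region, neurochemical) matrix.

    Parameters
    ----------
    pooled:
        Output of :func:`microdial.meta.pool_dataset`.
    granularity:
        ``"compound"`` collapses across doses and peak times; ``"compound_dose"``
        keeps one row per (drug, dose) pairing, collapsing across peak times.
    rule:
        ``"min"`` (the default) takes the arithmetic minimum response;
        ``"max_deviation"`` takes the response furthest from the 100% baseline
        (ties broken toward the smaller value).
    """
    if pooled.empty:
        raise ValueError("cannot build an activity matrix from no pooled effects")
    if granularity == "compound":
        owner = ["drug"]
    elif granularity == "compound_dose":
        owner = ["drug", "dose"]
    else:
        raise ValueError(f"unknown granularity {granularity!r}")
    key = owner + list(TUPLE_LEVELS)
    if rule == "min":
        cells = pooled.groupby(key, sort=True)["effect_pct"].min()
    elif rule == "max_deviation":
        ordered = pooled.sort_values("effect_pct").assign(
            _dev=lambda d: (d["effect_pct"] - 100.0).abs()
        )
        # stable sort: among equal deviations the smaller value comes first
        ordered = ordered.sort_values("_dev", kind="stable", ascending=False)
        cells = ordered.groupby(key, sort=True)["effect_pct"].first()
    else:
        raise ValueError(f"unknown activity rule {rule!r}")
    matrix = cells.unstack(list(TUPLE_LEVELS))
    matrix = matrix.sort_index(axis=0).sort_index(axis=1)
    return matrix


def response_fingerprint(activity: pd.DataFrame) -> pd.DataFrame:
    """Ternarise an activity matrix against the 100% baseline.

    Cells > 100 map to +1, < 100 to -1, exactly 100 to 0; missing cells stay
    NaN ("not measured"). Non-positive activities are invalid.
    """
    vals = activity.to_numpy(dtype=float)
    if np.any(vals[~np.isnan(vals)] <= 0):
        raise ValueError("activity values must be positive percent-of-baseline")
    signs = np.sign(vals - 100.0)
    return pd.DataFrame(signs, index=activity.index, columns=activity.columns)


def fingerprint_long(fps: pd.DataFrame) -> pd.DataFrame:
    """Long-format (compound, brain_region, neurochemical, sign) view."""
    long = fps.stack(list(TUPLE_LEVELS), future_stack=True).dropna().rename("sign")
    out = long.reset_index()
    out.columns = ["compound", *TUPLE_LEVELS, "sign"]
    out["sign"] = out["sign"].astype(int)
    return out


def sign_census(fps: pd.DataFrame) -> dict[str, int]:
    """Counts of measured cells by sign (the fingerprint census)."""
    vals = fps.to_numpy(dtype=float)
    measured = ~np.isnan(vals)
    return {
        "n_measurements": int(measured.sum()),
        "n_up": int((vals == 1).sum()),
        "n_down": int((vals == -1).sum()),
        "n_no_change": int((vals == 0).sum()),
        "n_regions": int(fps.columns.get_level_values("brain_region").nunique()),
        "n_neurochemicals": int(fps.columns.get_level_values("neurochemical").nunique()),
    }


_FP_GENERATORS: dict[tuple[int, int], object] = {}


def _generator(radius: int, n_bits: int):
    key = (radius, n_bits)
    if key not in _FP_GENERATORS:
        _FP_GENERATORS[key] = rdFingerprintGenerator.GetMorganGenerator(
            radius=radius, fpSize=n_bits
        )
    return _FP_GENERATORS[key]


def chemical_fingerprint(
    smiles: str,
    n_bits: int = 2048,
    radius: int = 2,
    strip_salts: bool = True,
    strip_stereo: bool = True,
    name: str | None = None,
) -> np.ndarray:
    """Hashed circular fingerprint (radius 2, 2048 bits) of one molecule.

    The SMILES is parsed with RDKit; by default the largest fragment is kept
    (salt stripping) and stereochemistry removed, so input dialects map to one
    deterministic bit vector. Unparseable SMILES raise a ValueError naming the
    compound.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        who = name if name is not None else smiles
        raise ValueError(f"unparseable SMILES for compound {who!r}")
    if strip_salts and "." in smiles:
        frags = Chem.GetMolFrags(mol, asMols=True)
        mol = max(frags, key=lambda m: m.GetNumHeavyAtoms())
    if strip_stereo:
        Chem.RemoveStereochemistry(mol)
    # round-trip through canonical SMILES so equivalent inputs hash identically
    mol = Chem.MolFromSmiles(Chem.MolToSmiles(mol))
    fp = _generator(radius, n_bits).GetFingerprintAsNumPy(mol)
    return fp.astype(np.uint8)


def chemical_fingerprint_frame(
    annotations: pd.DataFrame, n_bits: int = 2048, radius: int = 2
) -> pd.DataFrame:
    """Fingerprints for every annotated compound with a SMILES string.

    Compounds with an empty SMILES are skipped; unparseable SMILES raise,
    naming the compound.
    """
    rows, idx = [], []
    for compound, row in annotations.iterrows():
        smi = row["smiles"]
        if not smi:
            continue
        rows.append(chemical_fingerprint(smi, n_bits=n_bits, radius=radius, name=compound))
        idx.append(compound)
    if not rows:
        raise ValueError("no compound has a SMILES annotation")
    return pd.DataFrame(
        np.vstack(rows), index=pd.Index(idx, name="compound"),
        columns=pd.RangeIndex(n_bits, name="bit"),
    )


def fingerprint_hex(fp: np.ndarray) -> str:
    """Hex encoding of a bit vector for compact on-disk export."""
    return np.packbits(fp.astype(np.uint8)).tobytes().hex()
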