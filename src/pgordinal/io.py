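"""Delimited-text I/O for phenotypes, designs, relationship matrices and
posterior artifacts.

Formats (all CSV):

* phenotype table — columns ``line_id``, ``y`` (ordinal category 1..C);
  extra columns such as ``replicate`` or ``env`` are carried along but
  ignored by the model;
* design / marker matrix — first column ``line_id``, remaining columns
  numeric covariates or marker codes (one row per line);
* relationship matrix — square, header row and first column are line ids.

Outputs: posterior-summary table (parameter, mean, sd, 2.5%, 97.5%),
per-category probability table, a JSON manifest sufficient to re-run the
job bit-identically, and an ``.npz`` chain archive holding the raw
post-burn-in draws (arrays named as in ``PosteriorSamples.draws``).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model_core import OrdinalDataset, PosteriorSamples, ValidationError

__all__ = [
    "read_phenotypes",
    "read_design",
    "read_relationship",
    "assemble_dataset",
    "write_dataset",
    "write_posterior_summary",
    "write_probability_table",
    "write_chain_archive",
    "read_chain_archive",
    "write_manifest",
]


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("line_id", "y"):
        if col not in df.columns:
            raise ValidationError(f"phenotype file {path} lacks column {col!r}")
    if df["y"].isna().any() or (df["y"] != df["y"].astype(int)).any():
        raise ValidationError("phenotype column y must be integer categories")
    df["y"] = df["y"].astype(int)
    return df


def read_design(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    first = df.columns[0]
    if first != "line_id":
        raise ValidationError(
            f"design file {path} must have 'line_id' as its first column, "
            f"got {first!r}"
        )
    df = df.set_index("line_id")
    if df.isna().any().any():
        raise ValidationError(
            "design matrix contains missing values; impute or filter markers "
            "upstream — this package requires a complete X"
        )
    return df


def read_relationship(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ValidationError(f"relationship matrix {path} is not square")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def assemble_dataset(
    pheno: pd.DataFrame,
    design: pd.DataFrame,
    relationship: pd.DataFrame | None = None,
    C: int | None = None,
    center: bool = False,
) -> tuple[OrdinalDataset, list]:
    """Join phenotypes to the per-line design and optional G.

    Returns the dataset and the ordered list of line ids (index i → id).
    ``center`` subtracts column means from X (recommended for marker codes
    in ridge mode, where the thresholds absorb the resulting shift).
    """
    ids = pheno["line_id"].astype(str)
    design = design.copy()
    design.index = design.index.astype(str)
    missing = sorted(set(ids) - set(design.index))
    if missing:
        raise ValidationError(f"lines missing from design: {missing[:5]}...")
    line_ids = list(dict.fromkeys(ids))  # first-appearance order
    line_index = {lid: i for i, lid in enumerate(line_ids)}
    line_of = np.array([line_index[i] for i in ids])
    X_lines = design.loc[line_ids].to_numpy(dtype=float)
    X = X_lines[line_of]
    if center:
        X = X - X.mean(axis=0, keepdims=True)
    G = None
    if relationship is not None:
        missing_g = sorted(set(line_ids) - set(relationship.index))
        if missing_g:
            raise ValidationError(f"lines missing from G: {missing_g[:5]}...")
        G = relationship.loc[line_ids, line_ids].to_numpy(dtype=float)
    y = pheno["y"].to_numpy()
    return OrdinalDataset(y, X, line_of, G=G, C=C), line_ids


def write_dataset(out_dir, data: OrdinalDataset, line_ids=None, prefix: str = "") -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if line_ids is None:
        line_ids = [f"L{i + 1}" for i in range(data.I)]
    pheno = pd.DataFrame(
        {"line_id": [line_ids[i] for i in data.line_of], "y": data.y}
    )
    pheno.to_csv(out / f"{prefix}phenotypes.csv", index=False)
    # one design row per line (X is constant within line in the simulated
    # designs; for observation-level covariates write per-observation rows)
    first_obs = np.array([np.argmax(data.line_of == i) for i in range(data.I)])
    per_line = all(
        np.allclose(data.X[data.line_of == i], data.X[first_obs[i]])
        for i in range(data.I)
    )
    if per_line:
        design = pd.DataFrame(
            data.X[first_obs],
            columns=[f"x{j + 1}" for j in range(data.p)],
        )
        design.insert(0, "line_id", line_ids)
    else:
        design = pd.DataFrame(
            data.X, columns=[f"x{j + 1}" for j in range(data.p)]
        )
        design.insert(0, "line_id", [line_ids[i] for i in data.line_of])
    design.to_csv(out / f"{prefix}design.csv", index=False)


def write_posterior_summary(path, samples: PosteriorSamples, alpha: float = 0.05) -> None:
    samples.summary(alpha=alpha).to_csv(path, index=False)


def write_probability_table(path, probs) -> None:
    """Observation-averaged per-category point and interval estimates."""
    point = probs.probs.mean(axis=0)
    rows = {"category": np.arange(1, point.size + 1), "mean": point}
    if probs.lower is not None:
        rows["lower"] = probs.lower.mean(axis=0)
        rows["upper"] = probs.upper.mean(axis=0)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_chain_archive(path, samples: PosteriorSamples) -> None:
    np.savez_compressed(
        path, link=np.array(samples.link), C=np.array(samples.C), **samples.draws
    )


def read_chain_archive(path) -> PosteriorSamples:
    with np.load(path, allow_pickle=False) as z:
        link = str(z["link"])
        C = int(z["C"])
        draws = {k: z[k] for k in z.files if k not in ("link", "C")}
    return PosteriorSamples(draws, C=C, link=link)


def config_hash(payload: dict) -> str:
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_manifest(out_dir, payload: dict) -> None:
    payload = dict(payload)
    payload["config_hash"] = config_hash(payload)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "manifest.json", "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
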