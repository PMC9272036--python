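"""Readers and writers for genotype/phenotype tables and fit reports.

Genotype input comes in two dialects: PLINK ``.raw``-style (six metadata
columns FID IID PAT MAT SEX PHENOTYPE followed by per-SNP dosages named
like ``rs123_A``) and a plain numeric matrix with a header. All tables are
tab-delimited text.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import CausalCurve, PolyMRResults
from .simulate import CausalFunction, SimulatedDataset, SimulationSettings

logger = logging.getLogger(__name__)

__all__ = [
    "read_genotypes",
    "read_phenotypes",
    "align_samples",
    "write_dataset",
    "write_report",
    "read_settings",
    "settings_to_dict",
]

RAW_META_COLUMNS = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def _strip_allele_suffix(name: str) -> str:
    # "rs123_A" -> "rs123"; tolerate names without a suffix
    if "_" in name and name.rsplit("_", 1)[1].isalpha():
        return name.rsplit("_", 1)[0]
    return name


def read_genotypes(
    path: str | Path, dialect: str = "auto"
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Read a dosage table.

    Returns ``(dosages, sample_ids, snp_ids)`` where ``dosages`` is a
    DataFrame indexed by sample id with one column per SNP. Samples with
    any missing dosage are kept (flagged by NaN) for complete-case handling
    downstream.
    """
    path = Path(path)
    head = pd.read_csv(path, sep="\t", nrows=0)
    if dialect == "auto":
        dialect = "raw" if list(head.columns[:6]) == RAW_META_COLUMNS else "matrix"
    if dialect not in ("raw", "matrix"):
        raise ValueError(f"unknown genotype dialect {dialect!r}")

    df = pd.read_csv(
        path, sep="\t", na_values=["NA", "nan", ""], float_precision="round_trip"
    )
    if dialect == "raw":
        if list(df.columns[:6]) != RAW_META_COLUMNS:
            raise ValueError(
                f"{path}: .raw dialect requires leading columns {RAW_META_COLUMNS}"
            )
        ids = df["IID"].astype(str).tolist()
        dosage = df.iloc[:, 6:].copy()
        dosage.columns = [_strip_allele_suffix(c) for c in dosage.columns]
    else:
        ids = [str(i) for i in range(len(df))]
        dosage = df.copy()

    for col in dosage.columns:
        if not pd.api.types.is_numeric_dtype(dosage[col]):
            bad = dosage[col].apply(
                lambda v: pd.notna(v) and not isinstance(v, (int, float, np.number))
            )
            row = int(np.flatnonzero(bad.to_numpy())[0]) if bad.any() else 0
            raise ValueError(
                f"{path}: non-numeric dosage in column {col!r}, data row {row}"
            )
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"{path}: duplicate sample ids {dupes[:5]}")

    n_flagged = int(dosage.isna().any(axis=1).sum())
    if n_flagged:
        logger.info("%s: %d samples have missing dosages", path, n_flagged)
    dosage.index = pd.Index(ids, name="IID")
    return dosage, ids, list(dosage.columns)


def read_phenotypes(
    path: str | Path, exposure_col: str, outcome_col: str
) -> pd.DataFrame:
    """Read a tab-delimited phenotype table with named columns.

    Returns a DataFrame with columns ``exposure`` and ``outcome``, indexed
    by sample id if an ``IID`` (or ``FID``) column is present, else by row
    number.
    """
    path = Path(path)
    df = pd.read_csv(
        path, sep="\t", na_values=["NA", "nan", ""], float_precision="round_trip"
    )
    for col in (exposure_col, outcome_col):
        if col not in df.columns:
            raise KeyError(
                f"{path}: column {col!r} not found; available: {list(df.columns)}"
            )
    id_col = next((c for c in ("IID", "FID") if c in df.columns), None)
    idx = (
        pd.Index(df[id_col].astype(str), name="IID")
        if id_col
        else pd.Index([str(i) for i in range(len(df))], name="IID")
    )
    out = pd.DataFrame(
        {"exposure": df[exposure_col].to_numpy(), "outcome": df[outcome_col].to_numpy()},
        index=idx,
    )
    n_missing = int(out.isna().any(axis=1).sum())
    if n_missing:
        logger.info("%s: %d samples missing exposure or outcome", path, n_missing)
    return out


def align_samples(
    genotypes: pd.DataFrame, phenotypes: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Join genotype and phenotype tables on sample id.

    Returns ``(G, exposure, outcome, ids)`` for the intersection of samples,
    in genotype-file order; phenotype-only or genotype-only samples are
    dropped with a warning.
    """
    common = genotypes.index.intersection(phenotypes.index)
    n_drop = (len(genotypes) - len(common)) + (len(phenotypes) - len(common))
    if n_drop:
        logger.warning("sample alignment dropped %d unmatched records", n_drop)
    if len(common) == 0:
        raise ValueError("no overlapping sample ids between genotypes and phenotypes")
    keep = [i for i in genotypes.index if i in set(common)]
    G = genotypes.loc[keep]
    ph = phenotypes.loc[keep]
    return (
        G.to_numpy(float),
        ph["exposure"].to_numpy(float),
        ph["outcome"].to_numpy(float),
        list(keep),
    )


def _function_to_dict(f: CausalFunction) -> dict:
    return {
        "family": f.family,
        "coefficients": list(f.coefficients),
        "scale": f.scale,
        "steepness": f.steepness,
    }


def settings_to_dict(settings: SimulationSettings) -> dict:
    d = {
        "n_samples": settings.n_samples,
        "n_causal_snps": settings.n_causal_snps,
        "heritability": settings.heritability,
        "q_x": settings.q_x,
        "q_y": settings.q_y,
        "q_y2": settings.q_y2,
        "gwas_p_threshold": settings.gwas_p_threshold,
        "outcome_noise_sd": settings.outcome_noise_sd,
        "seed": settings.seed,
        "causal_function": _function_to_dict(settings.causal_function),
    }
    return d


def read_settings(path: str | Path) -> SimulationSettings:
    """Load simulation settings from a flat YAML config.

    A ``preset`` key loads a named scenario; any other keys override its
    fields. The causal function is either a nested ``causal_function`` block
    or implied by the preset.
    """
    from .simulate import get_scenario

    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    preset = cfg.pop("preset", None)
    fn_cfg = cfg.pop("causal_function", None)
    if fn_cfg is not None:
        cfg["causal_function"] = CausalFunction(
            family=fn_cfg.get("family", "polynomial"),
            coefficients=tuple(fn_cfg.get("coefficients", (0.0,))),
            scale=float(fn_cfg.get("scale", 0.1)),
            steepness=float(fn_cfg.get("steepness", 1.0)),
        )
    if preset is not None:
        return get_scenario(preset, **cfg)
    return SimulationSettings(**cfg)


def write_dataset(dataset: SimulatedDataset, prefix: str | Path) -> dict[str, Path]:
    """Write a simulated dataset as text files.

    ``<prefix>.raw`` holds the standardized dosages in PLINK .raw column
    layout (full float precision so a read round-trips bit-exactly),
    ``<prefix>.pheno.tsv`` the exposure and outcome, and
    ``<prefix>.truth.yaml`` the generative truth (β, causal function,
    settings echo).
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = dataset.genotypes.shape
    snp_ids = [f"snp{i + 1}_A" for i in range(m)]
    ids = [f"id{i + 1}" for i in range(n)]

    geno = pd.DataFrame(dataset.genotypes, columns=snp_ids)
    meta = pd.DataFrame(
        {
            "FID": ids,
            "IID": ids,
            "PAT": 0,
            "MAT": 0,
            "SEX": 0,
            "PHENOTYPE": -9,
        }
    )
    raw_path = prefix.with_suffix(".raw")
    pd.concat([meta, geno], axis=1).to_csv(raw_path, sep="\t", index=False)

    pheno_path = Path(f"{prefix}.pheno.tsv")
    pd.DataFrame(
        {"IID": ids, "exposure": dataset.exposure, "outcome": dataset.outcome}
    ).to_csv(pheno_path, sep="\t", index=False)

    truth_path = Path(f"{prefix}.truth.yaml")
    truth = {
        "settings": settings_to_dict(dataset.settings),
        "true_beta": [float(b) for b in dataset.true_beta],
        "mafs": [float(p) for p in dataset.mafs],
    }
    with open(truth_path, "w") as fh:
        yaml.safe_dump(truth, fh, sort_keys=False)
    return {"genotypes": raw_path, "phenotypes": pheno_path, "truth": truth_path}


def write_report(
    results: PolyMRResults, curve: CausalCurve | None, prefix: str | Path
) -> dict[str, Path]:
    """Write the fit report: coefficient table, covariance, curve table and
    a human-readable summary. Deterministic given the fit; numeric tables
    use 10 significant digits."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    coef_path = Path(f"{prefix}.coefficients.tsv")
    results.coefficient_table().to_csv(coef_path, sep="\t", index=False, float_format="%.10g")
    paths["coefficients"] = coef_path

    cov_path = Path(f"{prefix}.covariance.tsv")
    results.cov_params().to_csv(cov_path, sep="\t", float_format="%.10g")
    paths["covariance"] = cov_path

    if curve is not None:
        curve_path = Path(f"{prefix}.curve.tsv")
        curve.to_frame().to_csv(curve_path, sep="\t", index=False, float_format="%.10g")
        paths["curve"] = curve_path

    summary_path = Path(f"{prefix}.summary.txt")
    summary_path.write_text(results.summary() + "\n")
    paths["summary"] = summary_path
    return paths
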