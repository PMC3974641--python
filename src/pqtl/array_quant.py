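"""Antibody-array quantification and normalization.

Turns spot-level array features (signal/background/noise per spot, from
reverse-phase protein arrays or micro-western arrays) into a per-antibody,
per-sample expression matrix on a normalized log2 scale:

1. feature QC (drop spots with negative corrected intensity or S/N < 3),
2. log2 quantile normalization across arrays of a print (hybridization
   efficiency),
3. micro-western batch-median alignment,
4. sample-load correction: relative expression of sample j on array p is
   mu_jp - lambda_j with lambda_j the median of sample j's normalized
   intensity over the arrays of the print,
5. replicate aggregation (technical replicates averaged; the platform with
   the higher median raw corrected intensity wins when an antibody was run
   on both),
6. antibody-level decile filtering on median intensity and technical CV.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ArrayFeatureTable",
    "ProteinMatrix",
    "feature_qc",
    "log2_quantile_normalize",
    "sample_load_normalize",
    "batch_correct_mwa",
    "aggregate_replicates",
    "decile_filter",
    "quantify_features",
]

FEATURE_COLUMNS = [
    "array_id",
    "batch_id",
    "platform",
    "individual",
    "thaw",
    "tech_rep",
    "antibody",
    "signal",
    "background",
    "noise_sd",
]

PLATFORMS = ("RPPA", "MWA")


def _check_features(features: pd.DataFrame) -> None:
    missing = [c for c in FEATURE_COLUMNS if c not in features.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    if len(features) and (features["noise_sd"] <= 0).any():
        raise ValueError("noise_sd must be positive")
    if len(features) and not features["platform"].isin(PLATFORMS).all():
        raise ValueError(f"platform must be one of {PLATFORMS}")


class ArrayFeatureTable:
    """Thin validating wrapper over the spot-level feature DataFrame."""

    def __init__(self, table: pd.DataFrame):
        _check_features(table)
        self.table = table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class ProteinMatrix:
    """Antibody x (individual, thaw) normalized log2 expression.

    ``values``: DataFrame, index antibody ids, columns a MultiIndex
    (individual, thaw).  ``provenance``: per-antibody platform choice,
    median raw corrected intensity, technical CV and QC flag.
    """

    values: pd.DataFrame
    provenance: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if not isinstance(self.values.columns, pd.MultiIndex):
            raise ValueError("ProteinMatrix columns must be (individual, thaw) pairs")
        if not self.values.index.is_unique:
            raise ValueError("duplicate antibody ids")

    @property
    def antibodies(self) -> list:
        return list(self.values.index)

    @property
    def individuals(self) -> list:
        return list(self.values.columns.get_level_values(0).unique())

    def individual_means(self) -> pd.DataFrame:
        """Average expression over thaws; antibodies x individuals."""
        return self.values.T.groupby(level=0).mean().T

    def long(self) -> pd.DataFrame:
        """Tidy (antibody, individual, thaw, value) view."""
        out = self.values.stack([0, 1], future_stack=True).rename("value").reset_index()
        out.columns = ["antibody", "individual", "thaw", "value"]
        return out


# ---------------------------------------------------------------------------


def feature_qc(features: pd.DataFrame, snr_min: float = 3.0) -> pd.DataFrame:
    """Drop spots with background-subtracted intensity < 0 or S/N < snr_min.

    S/N is (signal - background)/noise_sd.  Exclusion counts per array are
    attached as ``.attrs['qc_excluded']``.
    """
    _check_features(features)
    if len(features) == 0:
        warnings.warn("empty feature table passed to feature_qc")
        return features.copy()
    corrected = features["signal"] - features["background"]
    keep = (corrected >= 0) & (corrected / features["noise_sd"] >= snr_min)
    out = features[keep].reset_index(drop=True)
    excl = features.loc[~keep].groupby("array_id").size()
    out.attrs["qc_excluded"] = excl.to_dict()
    return out


def log2_quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize log2 intensities so every array shares one distribution.

    ``matrix`` is samples x arrays of positive corrected intensities.  Each
    column is mapped, rank for rank, onto the mean of the sorted log2 values
    across columns; ties within a column receive the mean target of their
    tied ranks.  Columns that are entirely missing are dropped with a warning.
    """
    mat = matrix.copy().astype(float)
    mat[mat <= 0] = np.nan  # nonpositive intensities are unquantifiable, not clamped
    all_nan = mat.isna().all(axis=0)
    if all_nan.any():
        warnings.warn(f"dropping all-missing arrays: {list(mat.columns[all_nan])}")
        mat = mat.loc[:, ~all_nan]
    logm = np.log2(mat)
    n = len(logm)
    # mean of sorted values across arrays, interpolating where counts differ
    grid = np.linspace(0, 1, n)
    sorted_cols = []
    for c in logm.columns:
        col = logm[c].dropna().sort_values().to_numpy()
        if col.size == n:
            sorted_cols.append(col)
        else:
            sorted_cols.append(np.interp(grid, np.linspace(0, 1, col.size), col))
    target = np.mean(sorted_cols, axis=0)
    out = pd.DataFrame(index=logm.index, columns=logm.columns, dtype=float)
    from scipy.stats import rankdata

    for c in logm.columns:
        col = logm[c]
        obs = col.dropna()
        ranks = rankdata(obs, method="average")  # midranks: ties share a target
        scale = (len(obs) - 1) / max(n - 1, 1)
        pos = (ranks - 1) / max(len(obs) - 1, 1) * (n - 1)
        vals = np.interp(pos, np.arange(n), target)
        out.loc[obs.index, c] = vals
    return out


def sample_load_normalize(mu: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Correct for per-sample total protein load across the arrays of a print.

    ``mu`` is samples x arrays of normalized log2 intensities.  The load
    effect lambda_j of sample j is the median of its values over arrays;
    relative expression is mu_jp - lambda_j.  Samples observed on no array
    yield missing output with a warning.
    """
    lam = mu.median(axis=1, skipna=True)
    empty = lam.isna()
    if empty.any():
        warnings.warn(f"samples observed on no array: {list(mu.index[empty])}")
    return mu.sub(lam, axis=0), lam.rename("lambda")


def batch_correct_mwa(expression: pd.DataFrame, batch: pd.Series) -> pd.DataFrame:
    """Equalize batch medians of micro-western expression values.

    ``expression`` is samples x arrays; ``batch`` maps array -> batch id.
    Each batch's location is shifted so batch medians coincide with the
    global median; within-batch rank order is untouched.  Batches with < 2
    samples pass through with a warning.
    """
    batch = batch.reindex(expression.columns)
    global_med = float(np.nanmedian(expression.to_numpy(dtype=float)))
    out = expression.copy()
    for b, cols in expression.columns.groupby(batch.to_numpy()).items():
        block = expression[list(cols)]
        if block.notna().sum().sum() < 2:
            warnings.warn(f"batch {b} has <2 values; passed through")
            continue
        med = float(np.nanmedian(block.to_numpy(dtype=float)))
        out[list(cols)] = block - (med - global_med)
    return out


def aggregate_replicates(per_platform: dict[str, pd.DataFrame]) -> tuple[pd.DataFrame, pd.Series]:
    """Collapse platforms: average within-platform replicates, pick one platform.

    ``per_platform`` maps platform -> DataFrame indexed by antibody with a
    (individual, thaw) column MultiIndex, with ``.attrs['median_intensity']``
    a per-antibody Series of median raw corrected intensities.  Antibodies
    measured on both platforms keep the platform with the higher median raw
    intensity; ties prefer RPPA (single-band antibodies).  Returns the merged
    matrix and a per-antibody Series of the chosen platform.
    """
    choice: dict = {}
    for plat, df in per_platform.items():
        med = df.attrs.get("median_intensity", pd.Series(dtype=float))
        for ab in df.index:
            m = float(med.get(ab, np.nan))
            if ab not in choice:
                choice[ab] = (plat, m)
            else:
                prev_plat, prev_m = choice[ab]
                if np.isnan(prev_m) or (not np.isnan(m) and m > prev_m):
                    choice[ab] = (plat, m)
                elif m == prev_m and plat == "RPPA":
                    choice[ab] = (plat, m)
    rows = []
    for ab, (plat, _) in choice.items():
        rows.append(per_platform[plat].loc[ab])
    merged = pd.DataFrame(rows)
    merged.index.name = "antibody"
    platform_of = pd.Series({ab: plat for ab, (plat, _) in choice.items()}, name="platform")
    return merged, platform_of


def decile_filter(
    matrix: pd.DataFrame,
    provenance: pd.DataFrame,
    low_intensity_q: float = 0.10,
    high_cv_q: float = 0.90,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag antibodies in the bottom intensity decile or top technical-CV decile.

    Computed per platform from ``provenance`` (columns platform,
    median_intensity, tech_cv).  Thresholds are linear-interpolation
    percentiles; ties at the boundary are flagged (inclusive, conservative).
    Platforms with fewer than 10 antibodies skip the filter with a warning.
    Returns the retained matrix and provenance annotated with ``qc_flag``.
    """
    prov = provenance.copy()
    prov["qc_flag"] = ""
    for plat, grp in prov.groupby("platform"):
        if len(grp) < 10:
            warnings.warn(f"platform {plat}: <10 antibodies, decile filter skipped")
            continue
        lo = np.percentile(grp["median_intensity"].dropna(), 100 * low_intensity_q)
        hi = np.percentile(grp["tech_cv"].dropna(), 100 * high_cv_q)
        dim = grp.index[grp["median_intensity"] <= lo]
        noisy = grp.index[grp["tech_cv"] >= hi]
        prov.loc[dim, "qc_flag"] = prov.loc[dim, "qc_flag"] + "low_intensity;"
        prov.loc[noisy, "qc_flag"] = prov.loc[noisy, "qc_flag"] + "high_cv;"
    keep = prov.index[prov["qc_flag"] == ""]
    return matrix.loc[matrix.index.intersection(keep)], prov


# ---------------------------------------------------------------------------


def _platform_quantify(features: pd.DataFrame) -> pd.DataFrame:
    """Quantify one platform's spots into antibody x (individual, thaw) values."""
    feats = features.copy()
    feats["corrected"] = feats["signal"] - feats["background"]
    feats["sample"] = list(zip(feats["individual"], feats["thaw"]))
    # technical replicates averaged per (array, antibody, sample)
    cell = (
        feats.groupby(["array_id", "antibody", "sample"], sort=False)["corrected"]
        .agg(["mean", "std"])
        .reset_index()
    )
    # per-antibody technical CV: median over samples of sd/mean on raw intensities
    with np.errstate(invalid="ignore", divide="ignore"):
        cell["cv"] = cell["std"] / cell["mean"]
    tech_cv = cell.groupby("antibody")["cv"].median()
    median_intensity = cell.groupby("antibody")["mean"].median()

    mat = cell.pivot_table(index="sample", columns="array_id", values="mean", aggfunc="mean")
    mu = log2_quantile_normalize(mat)

    if (features["platform"] == "MWA").any():
        batch_of = features.drop_duplicates("array_id").set_index("array_id")["batch_id"]
        if batch_of.nunique() > 1:
            mu = batch_correct_mwa(mu, batch_of)

    rel, _ = sample_load_normalize(mu)

    array_ab = features.drop_duplicates("array_id").set_index("array_id")["antibody"]
    rel.columns = [array_ab[a] for a in rel.columns]
    # average arrays measuring the same antibody (within-platform replicates)
    out = rel.T.groupby(level=0).mean()
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["individual", "thaw"])
    out = out.sort_index(axis=1)
    out.attrs["median_intensity"] = median_intensity
    out.attrs["tech_cv"] = tech_cv
    return out


def quantify_features(
    features: pd.DataFrame,
    snr_min: float = 3.0,
    apply_decile_filter: bool = True,
) -> ProteinMatrix:
    """Full quantification pipeline: spots in, ProteinMatrix out."""
    clean = feature_qc(features, snr_min=snr_min)
    per_platform: dict[str, pd.DataFrame] = {}
    prov_parts = []
    for plat, grp in clean.groupby("platform", sort=False):
        q = _platform_quantify(grp)
        per_platform[plat] = q
        prov_parts.append(
            pd.DataFrame(
                {
                    "platform": plat,
                    "median_intensity": q.attrs["median_intensity"],
                    "tech_cv": q.attrs["tech_cv"],
                }
            )
        )
    merged, platform_of = aggregate_replicates(per_platform)
    prov = pd.concat(prov_parts)
    # keep each antibody's provenance row for its chosen platform
    chosen = [platform_of.get(ab) == plat for ab, plat in zip(prov.index, prov["platform"])]
    prov = prov[chosen]
    prov.index.name = "antibody"
    if apply_decile_filter:
        kept, prov = decile_filter(merged, prov)
    else:
        kept, prov = merged, prov.assign(qc_flag="")
    return ProteinMatrix(values=kept.sort_index(), provenance=prov.sort_index())
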