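"""Tabular input handling, covariate correction, and downstream summaries.

The pipeline mirrors a typical structural-imaging genetics study: region
volumes are corrected for age, sex and whole-brain volume by linear
regression, regions are centred and scaled (genotypes centred only), the
SEM is fitted, and the latent scores are summarised against diagnosis by
one-way ANOVA, with SNP-to-latent associations Bonferroni-corrected over
all m x p tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


class DataError(ValueError):
    """Malformed or inconsistent study tables."""


@dataclass
class StudyTables:
    """Aligned study inputs, indexed by sample id.

    ``grouping`` maps region_id -> group_code; regions absent from it are
    dropped at load time. ``covariates`` and ``diagnosis`` are optional.
    """

    genotypes: pd.DataFrame
    regions: pd.DataFrame
    grouping: pd.Series
    covariates: pd.DataFrame | None = None
    diagnosis: pd.Series | None = None
    dropped_regions: tuple = ()
    dropped_samples: int = 0


def _read_table(path, **kw) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, index_col=0, **kw)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        raise DataError(f"duplicate ids in {path.name}")
    return df


def load_study(
    genotypes,
    regions,
    grouping,
    covariates=None,
    diagnosis=None,
) -> StudyTables:
    """Read and align the study tables (CSV by default, TSV by extension).

    Samples are inner-joined on their ids across all tables; regions with
    no entry in the grouping file are dropped (logged). Non-numeric
    genotype or region cells raise with the offending row and column.
    """
    gt = _read_table(genotypes)
    rg = _read_table(regions)
    grp = _read_table(grouping)
    grp = pd.Series(grp.iloc[:, 0].values, index=grp.index, name="group_code")

    for name, df in (("genotypes", gt), ("regions", rg)):
        bad = df.map(lambda v: not isinstance(v, (int, float, np.integer, np.floating)) or pd.isna(v))
        if bad.any().any():
            r = bad.any(axis=1).idxmax()
            c = bad.loc[r].idxmax()
            raise DataError(f"non-numeric or missing value in {name} at row {r!r}, column {c!r}")

    unknown = [c for c in rg.columns if c not in grp.index]
    if unknown:
        log.warning("dropping %d region(s) with no group assignment: %s",
                    len(unknown), unknown)
        rg = rg.drop(columns=unknown)
    if rg.shape[1] == 0:
        raise DataError("no regions remain after applying the grouping")

    tables = [gt, rg]
    cov = _read_table(covariates) if covariates is not None else None
    if cov is not None:
        tables.append(cov)
    diag = None
    if diagnosis is not None:
        ddf = _read_table(diagnosis, dtype=str)
        diag = pd.Series(ddf.iloc[:, 0].values, index=ddf.index, name="diagnosis")
        tables.append(diag)

    common = tables[0].index
    for t in tables[1:]:
        common = common.intersection(t.index)
    if len(common) == 0:
        raise DataError("no overlapping sample ids across the study tables")
    n_dropped = max(len(t) for t in tables) - len(common)
    if n_dropped:
        log.warning("dropped %d sample(s) missing from at least one table", n_dropped)

    return StudyTables(
        genotypes=gt.loc[common],
        regions=rg.loc[common],
        grouping=grp.loc[rg.columns],
        covariates=cov.loc[common] if cov is not None else None,
        diagnosis=diag.loc[common] if diag is not None else None,
        dropped_regions=tuple(unknown),
        dropped_samples=int(n_dropped),
    )


def residualize_covariates(regions: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    """Residuals of each region on all covariates (OLS with intercept).

    Removes the linear effect of e.g. age, sex (coded 0/1) and whole-brain
    volume while keeping all remaining variation. Residuals have zero mean
    and zero sample correlation with every covariate, so the operation is
    idempotent.
    """
    R = np.asarray(regions, dtype=float)
    C = np.asarray(covariates, dtype=float)
    if np.isnan(R).any() or np.isnan(C).any():
        raise DataError("missing values are not allowed in regions or covariates")
    design = np.hstack([np.ones((len(C), 1)), C])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise DataError("covariates are collinear (design matrix rank deficient)")
    beta, *_ = np.linalg.lstsq(design, R, rcond=None)
    resid = R - design @ beta
    return pd.DataFrame(resid, index=regions.index, columns=regions.columns)


def standardize(genotypes, regions, scale_regions: bool = True):
    """Centre genotypes; centre (and by default scale to unit sd) regions.

    Region scaling compensates for the larger raw variance of larger
    structures. Returns arrays/frames matching the input types. Constant
    columns are rejected by name.
    """
    def _as_frame(obj, prefix):
        if isinstance(obj, pd.DataFrame):
            return obj.astype(float), True
        arr = np.atleast_2d(np.asarray(obj, dtype=float))
        cols = [f"{prefix}{i + 1}" for i in range(arr.shape[1])]
        return pd.DataFrame(arr, columns=cols), False

    gdf, g_was_frame = _as_frame(genotypes, "snp")
    xdf, x_was_frame = _as_frame(regions, "region")
    for name, df in (("genotype", gdf), ("region", xdf)):
        sd = df.std(ddof=0)
        if (sd == 0).any():
            raise DataError(f"constant {name} column(s): {list(sd.index[sd == 0])}")
    g_c = gdf - gdf.mean()
    x_c = xdf - xdf.mean()
    if scale_regions:
        x_c = x_c / x_c.std(ddof=0)
    if not g_was_frame:
        g_c = g_c.values
    if not x_was_frame:
        x_c = x_c.values
    return g_c, x_c


def bonferroni_adjust(p_matrix: np.ndarray, alpha: float = 0.05):
    """Bonferroni correction over all entries of a p-value matrix.

    Returns (adjusted, flags): adjusted = min(1, p * n_tests) with n_tests
    the total number of entries, and flags = adjusted < alpha.
    """
    p = np.asarray(p_matrix, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    adjusted = np.minimum(1.0, p * p.size)
    return adjusted, adjusted < alpha


def anova_by_group(scores, labels) -> pd.DataFrame:
    """One-way ANOVA of each latent score column across diagnosis groups.

    Returns a frame with one row per latent (F statistic and p value).
    Requires at least two groups with at least two samples each.
    """
    values = scores.values if hasattr(scores, "values") else np.asarray(scores)
    if values.ndim == 1:
        values = values[:, None]
    labels = np.asarray(labels)
    groups = pd.unique(labels)
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two diagnosis groups")
    counts = [int((labels == lv).sum()) for lv in groups]
    if min(counts) < 2:
        raise ValueError("every diagnosis group needs at least two samples")
    names = getattr(scores, "group_ids", None) or [f"latent{i+1}" for i in range(values.shape[1])]
    rows = []
    for j, name in enumerate(names):
        samples = [values[labels == lv, j] for lv in groups]
        with np.errstate(invalid="ignore", divide="ignore"):
            F, p = stats.f_oneway(*samples)
        if not np.isfinite(F):
            rows.append({"latent": name, "F": np.nan, "p": np.nan, "degenerate": True})
        else:
            rows.append({"latent": name, "F": float(F), "p": float(p), "degenerate": False})
    return pd.DataFrame(rows).set_index("latent")


def train_validation_split(sample_ids, seed: int = 0):
    """Split sample ids into two disjoint halves by a seeded shuffle.

    With an odd count the training half receives the extra sample.
    Returns (train_ids, validation_ids) as numpy arrays.
    """
    ids = np.asarray(sample_ids)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    half = (len(ids) + 1) // 2
    return ids[order[:half]], ids[order[half:]]
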