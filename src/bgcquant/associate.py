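"""Rank-correlation association of BGC abundances with BMI and taxa.

Per-cluster association uses Spearman's rank correlation (average ranks for
ties; p-value from the large-sample t approximation, with an exact
permutation option for very small n) with Benjamini-Hochberg adjustment
across the tested family.  Three analyses are provided: per-cluster
abundance vs BMI, per-sample mean abundance vs BMI, and a chosen feature
(typically one cluster's abundance) vs phylum-level relative abundances
from a MetaPhlAn-style taxonomic profile.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from bgcquant.errors import InputError, StageError
from bgcquant.quantify import AbundanceMatrix

logger = logging.getLogger(__name__)

#: note attached to features whose vector is constant (rho undefined)
UNDEFINED_CORRELATION = "undefined_correlation"


class ConstantInputError(StageError):
    """Spearman correlation is undefined for a constant vector."""


@dataclass(frozen=True)
class AssociationRecord:
    feature_id: str
    rho: float
    p_value: float
    q_value: float
    n: int


def spearman(
    x: Sequence[float], y: Sequence[float], method: str = "t-approx"
) -> tuple[float, float]:
    """Spearman's rank correlation with two-sided p-value.

    ``method`` is ``"t-approx"`` (default; average-rank ties, t distribution
    with n-2 degrees of freedom) or ``"exact"`` (full enumeration of rank
    permutations, n <= 10 only).

    Raises ConstantInputError when either vector is constant — rho is
    undefined there and never returned as silent NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise ValueError(f"need n >= 3 samples, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("constant input vector: correlation undefined")
    if method == "t-approx":
        res = stats.spearmanr(x, y)
        return float(res.statistic), float(res.pvalue)
    if method == "exact":
        return _spearman_exact(x, y)
    raise ValueError(f"unknown method {method!r}")


def _spearman_exact(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided permutation p-value by full enumeration (n <= 10)."""
    n = x.size
    if n > 10:
        raise ValueError("exact permutation enumeration limited to n <= 10")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    obs = _rank_corr(rx, ry)
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r = _rank_corr(rx, ry[list(perm)])
        total += 1
        if abs(r) >= abs(obs) - 1e-12:
            count += 1
    return float(obs), count / total


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    """Pearson correlation of two rank vectors (handles ties via the ranks)."""
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    return float(rx @ ry) / denom


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1, returned in the order of
    the input.  p-values outside (0, 1] are a hard error.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if p.size == 0:
        return np.array([])
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise InputError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def load_metadata(path: str | Path) -> pd.DataFrame:
    """Sample metadata TSV with columns sample_id, bmi[, group]."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if not {"sample_id", "bmi"}.issubset(df.columns):
        raise InputError(f"metadata file {path} needs columns sample_id, bmi")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise InputError(f"duplicate sample_id(s) in metadata: {dupes}")
    return df.set_index("sample_id")


def _align_bmi(abund: AbundanceMatrix, meta: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Intersect samples, dropping (and logging) samples with missing BMI."""
    bmi = meta["bmi"].astype(float)
    missing = bmi.index[bmi.isna()]
    if len(missing):
        logger.info("dropping %d sample(s) with missing BMI", len(missing))
        bmi = bmi.dropna()
    shared = abund.values.index.intersection(bmi.index)
    logger.info(
        "BMI association: %d/%d abundance samples matched to metadata",
        len(shared), abund.values.shape[0],
    )
    if len(shared) < 3:
        raise InputError(
            f"only {len(shared)} samples shared between abundances and metadata (need >= 3)"
        )
    return abund.values.loc[shared], bmi.loc[shared]


def _associate_vectors(
    features: pd.DataFrame, target: pd.Series
) -> pd.DataFrame:
    """Spearman of every feature column against ``target``; BH across the
    testable (non-constant) family; rows sorted by p then feature_id."""
    rows = []
    for feature_id in features.columns:
        vec = features[feature_id]
        try:
            rho, p = spearman(vec.values, target.values)
            rows.append((str(feature_id), rho, p, len(vec), ""))
        except ConstantInputError:
            rows.append((str(feature_id), np.nan, np.nan, len(vec), UNDEFINED_CORRELATION))
    df = pd.DataFrame(rows, columns=["feature_id", "rho", "p_value", "n", "note"])
    tested = df["note"] == ""
    df["q_value"] = np.nan
    if tested.any():
        # a perfect monotone relation yields p = 0 under the t approximation;
        # clamp to the smallest positive float so the step-up stays defined
        p_for_bh = np.clip(df.loc[tested, "p_value"].values, np.finfo(float).tiny, 1.0)
        df.loc[tested, "q_value"] = bh_adjust(p_for_bh)
    df = df.sort_values(
        ["note", "p_value", "feature_id"], na_position="last", kind="stable"
    ).reset_index(drop=True)
    return df[["feature_id", "rho", "p_value", "q_value", "n", "note"]]


def associate_bmi(
    abund: AbundanceMatrix,
    meta: pd.DataFrame,
    annotations: dict[str, tuple[str, str]] | None = None,
    cluster_genomes: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-cluster Spearman association of abundance with BMI.

    Returns one row per retained cluster with columns genome_id (if
    provided), cluster_id, best_hit / sm annotation (if provided), rho,
    p_value, q_value, n, note; sorted ascending by p-value with
    deterministic ties; constant clusters are excluded from the BH family
    and flagged ``undefined_correlation``.
    """
    values, bmi = _align_bmi(abund, meta)
    df = _associate_vectors(values, bmi).rename(columns={"feature_id": "cluster_id"})
    if cluster_genomes:
        df.insert(0, "genome_id", df["cluster_id"].map(cluster_genomes).fillna(""))
    if annotations:
        df["best_hit"] = df["cluster_id"].map(
            lambda c: annotations.get(c, ("", ""))[0]
        )
        df["sm"] = df["cluster_id"].map(lambda c: annotations.get(c, ("", ""))[1])
    return df


def mean_abundance_stat(
    abund: AbundanceMatrix, meta: pd.DataFrame
) -> tuple[pd.Series, float, float]:
    """Per-sample mean abundance over retained clusters (imputed cells
    included) and its Spearman correlation with BMI."""
    if abund.values.shape[1] == 0:
        raise StageError("no retained clusters: mean abundance undefined")
    means = abund.values.mean(axis=1)
    values, bmi = _align_bmi(abund, meta)
    rho, p = spearman(means.loc[values.index].values, bmi.values)
    return means, rho, p


def associate_taxa(feature: pd.Series, tax: pd.DataFrame) -> pd.DataFrame:
    """Spearman association of one feature vector against every phylum.

    ``tax`` is samples x phyla (relative abundance, percent).  Phyla absent
    (zero) in every shared sample are excluded and flagged; BH runs across
    the tested phyla.  Returns columns phylum, rho, p_value, q_value
    (the tables' FDR), n, note.
    """
    shared = tax.index.intersection(feature.index)
    if len(shared) < 3:
        raise InputError(
            f"only {len(shared)} samples shared between feature and taxa (need >= 3)"
        )
    tax = tax.loc[shared]
    feature = feature.loc[shared]
    absent = tax.columns[(tax == 0).all(axis=0)]
    if len(absent):
        logger.info("excluding %d phylum(a) absent from all samples", len(absent))
    present = tax.drop(columns=absent)
    df = _associate_vectors(present, feature).rename(columns={"feature_id": "phylum"})
    for ph in absent:
        df = pd.concat(
            [df, pd.DataFrame([{
                "phylum": str(ph), "rho": np.nan, "p_value": np.nan,
                "q_value": np.nan, "n": len(shared), "note": "absent_in_all_samples",
            }])],
            ignore_index=True,
        )
    return df


def load_metaphlan_profile(path: str | Path) -> pd.DataFrame:
    """Extract phylum-level rows from a merged MetaPhlAn-style profile.

    The profile has clade rows (``k__Bacteria|p__Firmicutes|...``) and one
    column per sample.  Rows whose clade terminates at the phylum rank
    (contains ``p__`` and nothing deeper) are kept; the result is transposed
    to samples x phyla with the ``p__`` prefix stripped.
    """
    df = pd.read_csv(path, sep="\t", comment=None)
    clade_col = df.columns[0]
    clades = df[clade_col].astype(str)
    is_phylum = clades.str.contains(r"p__") & ~clades.str.contains(r"\|c__")
    sub = df[is_phylum].copy()
    if sub.empty:
        raise InputError(f"no phylum-level rows (p__*) found in {path}")
    sub["phylum"] = sub[clade_col].str.extract(r"p__([^|]+)$")[0]
    sub = sub.drop(columns=[clade_col]).set_index("phylum")
    out = sub.T.astype(float)
    out.index.name = "sample_id"
    if (out.values < 0).any():
        raise InputError("negative relative abundance in taxonomic profile")
    return out


def write_association_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
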