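"""Plate-normalized Z-scores, hit selection and screen-level statistics.

Each well's three parameters (E-cad, Jun-A, Cyt-A percent areas) are
expressed in control-referenced standard-deviation units computed per
plate: ``z = (x - center(controls)) / scale(controls)``. The default anchor
is the untransfected junction-induced positive controls; robust mode uses
median and MAD*1.4826, moment mode mean and SD. Per-gene final scores are
the median over replicate experiments; a gene is a candidate when any
parameter's |median Z| exceeds the cutoff (default 1.65, strict).

The four-oligo validation rule: a gene is validated when two or more of
its single-oligo median Z-scores fall outside the cutoff in the same
direction; two up *and* two down is ambiguous.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator, TransformerMixin

log = logging.getLogger(__name__)

__all__ = [
    "PlateZScorer",
    "plate_zscores",
    "aggregate_and_select",
    "validate_oligos",
    "validate_oligo_table",
    "correlate_parameters",
    "test_normality",
]

RAW_COLS = ("ecad_raw", "juna_raw", "cyta_raw")
Z_COLS = ("z_ecad", "z_juna", "z_cyta")

_MAD_SCALE = 1.4826  # MAD -> SD for a normal distribution


class PlateZScorer(BaseEstimator, TransformerMixin):
    """Per-plate control-anchored Z-scoring as an sklearn transformer.

    Parameters
    ----------
    control_role : which wells anchor the normalization (default the
        junction-induced positive controls).
    robust : median/MAD*1.4826 when True (default; the screen data are
        non-Gaussian), mean/SD when False.
    group_cols : plate identity; include ``replicate`` when the same plate
        id recurs across independent experiments.

    Attributes
    ----------
    plate_stats_ : DataFrame indexed by the group columns with the center
        and scale used per parameter; zero-scale plates are flagged and
        their Z-scores left missing, never +/-inf.
    """

    def __init__(
        self,
        control_role: str = "pos_ctrl",
        robust: bool = True,
        group_cols: tuple = ("plate", "replicate"),
    ):
        self.control_role = control_role
        self.robust = robust
        self.group_cols = group_cols

    def _groups(self, X: pd.DataFrame) -> list[str]:
        return [c for c in self.group_cols if c in X.columns]

    def fit(self, X: pd.DataFrame, y=None):
        X = self._validate(X)
        groups = self._groups(X)
        recs = []
        for key, sub in X.groupby(groups, sort=True):
            ctrl = sub[sub["role"] == self.control_role]
            rec = dict(zip(groups, key if isinstance(key, tuple) else (key,)))
            rec["n_controls"] = len(ctrl)
            flagged = False
            for raw in RAW_COLS:
                vals = ctrl[raw].to_numpy(dtype=float)
                vals = vals[np.isfinite(vals)]
                if vals.size < 2:
                    raise ValueError(
                        f"plate group {key!r} has <2 finite "
                        f"{self.control_role} wells"
                    )
                if self.robust:
                    center = float(np.median(vals))
                    scale = _MAD_SCALE * float(np.median(np.abs(vals - center)))
                else:
                    center = float(vals.mean())
                    scale = float(vals.std(ddof=0))
                if scale == 0.0:
                    flagged = True
                rec[f"center_{raw}"] = center
                rec[f"scale_{raw}"] = scale
            rec["flagged"] = flagged
            if flagged:
                log.warning("plate group %r has zero control scale; flagged", key)
            recs.append(rec)
        self.plate_stats_ = pd.DataFrame(recs).set_index(groups)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = self._validate(X).copy()
        groups = self._groups(X)
        merged = X.merge(
            self.plate_stats_.reset_index(), on=groups, how="left", validate="m:1"
        )
        for raw, zc in zip(RAW_COLS, Z_COLS):
            scale = merged[f"scale_{raw}"].replace(0.0, np.nan)
            z = (merged[raw].astype(float) - merged[f"center_{raw}"]) / scale
            X[zc] = z.to_numpy()
        X["normalization"] = "robust" if self.robust else "moment"
        return X

    def _validate(self, X: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in ("role", *RAW_COLS) if c not in X.columns]
        if missing:
            raise ValueError(f"missing required columns: {missing}")
        return X


def plate_zscores(
    table: pd.DataFrame, control_role: str = "pos_ctrl", robust: bool = True
) -> pd.DataFrame:
    """Fit-and-transform convenience wrapper around :class:`PlateZScorer`."""
    return PlateZScorer(control_role=control_role, robust=robust).fit_transform(table)


def aggregate_and_select(
    zscores: pd.DataFrame, cutoff: float = 1.65
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Median-over-replicates per gene and strict-cutoff candidate calls.

    Only qc-passing replicate wells enter the medians; genes whose
    replicates all failed QC are excluded and returned in a rejects report.
    Candidate per parameter iff |median Z| > cutoff (strict: a median of
    exactly 1.65 is not a candidate); a gene is a candidate when any
    parameter qualifies. Phenotype multiplicity (single/double/triple)
    counts the qualifying parameters.
    """
    df = zscores[zscores["role"] == "sample"].copy()
    if "qc_pass" not in df.columns:
        df["qc_pass"] = True
    ok = df[df["qc_pass"].astype(bool)]
    rejected = sorted(set(df["gene"]) - set(ok["gene"]))
    rejects = pd.DataFrame({"gene": rejected, "reason": "all replicates failed QC"})

    agg = ok.groupby("gene", sort=True)[list(Z_COLS)].median()
    agg.columns = [f"median_{c}" for c in Z_COLS]
    for zc in Z_COLS:
        agg[f"candidate_{zc[2:]}"] = agg[f"median_{zc}"].abs() > cutoff
    cand_cols = [f"candidate_{zc[2:]}" for zc in Z_COLS]
    agg["n_phenotypes"] = agg[cand_cols].sum(axis=1).astype(int)
    agg["candidate"] = agg["n_phenotypes"] > 0
    agg["phenotype_multiplicity"] = agg["n_phenotypes"].map(
        {0: "none", 1: "single", 2: "double", 3: "triple"}
    )
    return agg.reset_index(), rejects


def validate_oligos(per_oligo_medians, cutoff: float = 1.0) -> str:
    """Apply the four-oligo rule to one gene's per-oligo median Z-scores.

    Returns one of ``validated_up``, ``validated_down``, ``ambiguous``,
    ``not_validated``. Fewer than 4 oligos is allowed with a warning.
    """
    z = np.asarray(per_oligo_medians, dtype=float)
    z = z[np.isfinite(z)]
    if z.size < 4:
        warnings.warn(f"only {z.size} oligo scores supplied (expected 4)")
    n_up = int((z > cutoff).sum())
    n_down = int((z < -cutoff).sum())
    if n_up >= 2 and n_down >= 2:
        return "ambiguous"
    if n_up >= 2:
        return "validated_up"
    if n_down >= 2:
        return "validated_down"
    return "not_validated"


def validate_oligo_table(
    oligo_medians: pd.DataFrame, cutoff: float = 1.0, param: str = "median_z_ecad"
) -> pd.DataFrame:
    """Per-gene validation calls from a (gene, oligo, median-Z) table."""
    calls = (
        oligo_medians.groupby("gene", sort=True)[param]
        .apply(lambda z: validate_oligos(z.to_numpy(), cutoff=cutoff))
        .rename("call")
        .reset_index()
    )
    calls["cutoff"] = cutoff
    calls["parameter"] = param
    return calls


def correlate_parameters(
    table: pd.DataFrame, pairs: list[tuple[str, str]] | None = None
) -> pd.DataFrame:
    """Pairwise Pearson correlations with two-sided significance.

    For each pair, reports R, the two-sided P (the F-test on the simple
    regression slope, identical to the squared-t test Pearson uses), n,
    and the fitted line for plotting. Constant columns give missing R.
    """
    if pairs is None:
        cols = [c for c in table.columns if c.startswith("median_z") or c in Z_COLS]
        pairs = [(a, b) for i, a in enumerate(cols) for b in cols[i + 1 :]]
    recs = []
    for a, b in pairs:
        sub = table[[a, b]].dropna()
        x, y = sub[a].to_numpy(float), sub[b].to_numpy(float)
        rec = {"x": a, "y": b, "n": len(sub)}
        if len(sub) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
            rec.update(r=np.nan, p=np.nan, slope=np.nan, intercept=np.nan)
        else:
            r, p = stats.pearsonr(x, y)
            fit = stats.linregress(x, y)
            rec.update(
                r=float(r),
                p=float(p),
                slope=float(fit.slope),
                intercept=float(fit.intercept),
                slope_stderr=float(fit.stderr),
            )
        recs.append(rec)
    return pd.DataFrame(recs)


def _shifted_log_skew(x: np.ndarray, delta: float) -> float:
    return float(stats.skew(np.log(x - x.min() + delta)))


def test_normality(values) -> dict:
    """Shapiro-Wilk W on raw and on skew-corrected log-transformed data.

    The log transform is a three-parameter shifted log ``log(x - c)`` with
    the shift chosen to minimize |sample skewness| — the standard
    skew-correction for testing log-Gaussianity when the location offset
    is unknown. Returns W and P for both versions plus the shift used.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 8:
        raise ValueError("need at least 8 finite values")
    if np.ptp(x) == 0:
        raise ValueError("constant input: normality test undefined")
    w_raw, p_raw = stats.shapiro(x)

    span = float(np.ptp(x))
    res = minimize_scalar(
        lambda u: abs(_shifted_log_skew(x, np.exp(u))),
        bounds=(np.log(1e-6 * span), np.log(1e4 * span)),
        method="bounded",
    )
    delta = float(np.exp(res.x))
    transformed = np.log(x - x.min() + delta)
    w_log, p_log = stats.shapiro(transformed)
    return {
        "w_raw": float(w_raw),
        "p_raw": float(p_raw),
        "w_log": float(w_log),
        "p_log": float(p_log),
        "shift": float(x.min() - delta),
        "n": int(x.size),
    }
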