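"""Binomial-logit fire-occurrence model and the VPD_P50 activity threshold.

The model is a single-predictor logistic regression of daily fire occurrence
on daily-maximum VPD, fitted per stratum (biome x sub-continental window):

    P(fire | VPD = v) = expit(beta0 + beta1 * v)

Its headline quantity is the *fire-activity threshold* VPD_P50 = -beta0/beta1,
the VPD at which the fitted probability of fire crosses 50%.  The standard
error of this ratio comes from first-order (delta-method) propagation of the
coefficient covariance, and the reported confidence interval is +/- 2 SE.
Model skill is summarised by the ROC AUC (trapezoidal over unique scores),
the true-positive rate at the 0.5 probability cutoff, and percent deviance
explained against the intercept-only model.

Usage follows the Model / Results convention::

    res = FireOccurrenceModel.from_dataframe(samples).fit()
    res.vpd_p50, res.ci_p50, res.auc
    print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit


class UnfittableError(ValueError):
    """Raised when a sample cannot support a logistic fit (e.g. one label)."""


class NonIncreasingResponseError(ValueError):
    """Raised when the fitted slope is not positive, so VPD_P50 is undefined."""


def vpd_p50(beta0: float, beta1: float) -> float:
    """The 50% fire-probability threshold -beta0/beta1 (kPa); needs beta1 > 0."""
    if not beta1 > 0:
        raise NonIncreasingResponseError(
            f"beta1={beta1:.4g} is not positive: fire probability does not "
            "increase with VPD, so a 50% threshold is undefined"
        )
    return -beta0 / beta1


def threshold_uncertainty(
    beta0: float, beta1: float, cov: np.ndarray
) -> tuple[float, tuple[float, float]]:
    """Delta-method SE of -beta0/beta1 and the +/- 2 SE confidence interval.

    With g = (-1/beta1, beta0/beta1^2), SE^2 = g @ cov @ g.  A non-finite
    covariance yields (nan, (nan, nan)) rather than an exception, so callers
    can flag the stratum and move on.
    """
    cov = np.asarray(cov, dtype=float)
    if cov.shape != (2, 2) or not np.all(np.isfinite(cov)):
        return float("nan"), (float("nan"), float("nan"))
    grad = np.array([-1.0 / beta1, beta0 / beta1**2])
    var = float(grad @ cov @ grad)
    se = float(np.sqrt(max(var, 0.0)))
    centre = vpd_p50(beta0, beta1)
    return se, (centre - 2.0 * se, centre + 2.0 * se)


def roc_auc(y: np.ndarray, scores: np.ndarray) -> float:
    """Trapezoidal AUC of the ROC over unique score thresholds.

    Ties in the score contribute half weight, so this equals the
    Mann-Whitney pair fraction exactly.  Invariant to strictly monotone
    transforms of the scores.  Requires both classes present.
    """
    y = np.asarray(y)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    order = np.argsort(scores)[::-1]
    y_sorted = y[order]
    s_sorted = scores[order]
    tps = np.cumsum(y_sorted == 1)
    fps = np.cumsum(y_sorted == 0)
    # keep only the last index of each tied score block
    last_of_block = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    tpr = np.r_[0.0, tps[last_of_block] / n_pos]
    fpr = np.r_[0.0, fps[last_of_block] / n_neg]
    return float(np.trapezoid(tpr, fpr))


@dataclass
class FireOccurrenceResults:
    """Fitted logistic occurrence model for one stratum.

    Carries the coefficients, their covariance, the VPD_P50 threshold with
    delta-method uncertainty, and skill diagnostics.  ``separated`` flags a
    perfectly separated sample, for which the threshold is the midpoint of
    the separating gap and the slope is effectively infinite.
    """

    stratum: str
    params: np.ndarray          # (beta0, beta1)
    cov_params: np.ndarray      # 2x2
    bse: np.ndarray
    vpd_p50: float              # kPa
    se_p50: float               # kPa
    ci_p50: tuple[float, float]
    auc: float
    tpr: float
    deviance_explained: float   # percent
    n_rows: int
    converged: bool
    separated: bool = False

    @property
    def beta0(self) -> float:
        return float(self.params[0])

    @property
    def beta1(self) -> float:
        return float(self.params[1])

    def predict(self, vpd: np.ndarray | float) -> np.ndarray | float:
        """Fitted fire probability at the given VPD (kPa)."""
        if self.separated:
            v = np.asarray(vpd, dtype=float)
            out = np.where(v > self.vpd_p50, 1.0, np.where(v < self.vpd_p50, 0.0, 0.5))
            return out if out.ndim else float(out)
        return expit(self.beta0 + self.beta1 * np.asarray(vpd, dtype=float))

    def summary(self) -> str:
        lines = [
            "Fire occurrence model (binomial GLM, logit link)",
            "=" * 56,
            f"stratum:             {self.stratum}",
            f"n rows:              {self.n_rows}",
            f"converged:           {self.converged}"
            + ("   [perfect separation]" if self.separated else ""),
            f"beta0 (intercept):   {self.beta0: .4f}  (SE {self.bse[0]:.4f})",
            f"beta1 (per kPa):     {self.beta1: .4f}  (SE {self.bse[1]:.4f})",
            "-" * 56,
            f"VPD_P50 [kPa]:       {self.vpd_p50: .4f}  (SE {self.se_p50:.4f})",
            f"95% CI (+/-2 SE):    ({self.ci_p50[0]:.4f}, {self.ci_p50[1]:.4f})",
            f"AUC:                 {self.auc:.4f}",
            f"TPR @ p>=0.5:        {self.tpr:.4f}",
            f"deviance explained:  {self.deviance_explained:.2f} %",
            "=" * 56,
        ]
        return "\n".join(lines)


class FireOccurrenceModel:
    """Logistic model of daily fire occurrence as a function of VPD."""

    def __init__(self, burned: np.ndarray, vpd: np.ndarray, stratum: str = "all"):
        burned = np.asarray(burned, dtype=float)
        vpd = np.asarray(vpd, dtype=float)
        if burned.shape != vpd.shape or burned.ndim != 1:
            raise ValueError("burned and vpd must be 1-D arrays of equal length")
        if not np.all(np.isfinite(vpd)):
            raise ValueError("non-finite VPD values in sample")
        if not set(np.unique(burned)) <= {0.0, 1.0}:
            raise ValueError("burned labels must be 0/1")
        self.burned = burned
        self.vpd = vpd
        self.stratum = stratum

    @classmethod
    def from_dataframe(cls, samples: pd.DataFrame, stratum: str | None = None) -> "FireOccurrenceModel":
        """Build from a sample table with ``vpd_kpa`` and ``burned`` columns."""
        if stratum is not None:
            samples = samples[samples["stratum"] == stratum]
        else:
            strata = samples["stratum"].unique() if "stratum" in samples else ["all"]
            stratum = str(strata[0]) if len(strata) == 1 else "pooled"
        return cls(samples["burned"].values, samples["vpd_kpa"].values, stratum=stratum)

    def _separation_gap(self) -> tuple[float, float] | None:
        pos = self.vpd[self.burned == 1]
        neg = self.vpd[self.burned == 0]
        if neg.max() < pos.min():
            return float(neg.max()), float(pos.min())
        return None

    def fit(self, tol: float = 1e-8, maxiter: int = 100) -> FireOccurrenceResults:
        """Maximum-likelihood fit; IRLS with tolerance on the deviance.

        Perfect separation is detected up front: the threshold is then
        reported as the midpoint of the separating gap with an
        infinite-slope flag instead of letting the optimiser diverge.
        """
        n_pos = int(np.sum(self.burned == 1))
        n_neg = int(np.sum(self.burned == 0))
        if n_pos < 2 or n_neg < 2:
            raise UnfittableError(
                f"stratum {self.stratum}: need >= 2 rows of each label, "
                f"got {n_pos} presences / {n_neg} absences"
            )
        gap = self._separation_gap()
        auc_val = roc_auc(self.burned, self.vpd)
        if gap is not None:
            mid = 0.5 * (gap[0] + gap[1])
            nan2 = np.full(2, np.nan)
            tpr = float(np.mean(self.vpd[self.burned == 1] >= mid))
            return FireOccurrenceResults(
                stratum=self.stratum,
                params=np.array([-np.inf, np.inf]),
                cov_params=np.full((2, 2), np.nan),
                bse=nan2,
                vpd_p50=mid,
                se_p50=float("nan"),
                ci_p50=(float("nan"), float("nan")),
                auc=auc_val,
                tpr=tpr,
                deviance_explained=100.0,
                n_rows=len(self.burned),
                converged=True,
                separated=True,
            )

        exog = sm.add_constant(self.vpd)
        glm = sm.GLM(self.burned, exog, family=sm.families.Binomial())
        fit = glm.fit(tol=tol, maxiter=maxiter)
        beta0, beta1 = (float(v) for v in fit.params)
        cov = np.asarray(fit.cov_params())
        p50 = vpd_p50(beta0, beta1)
        se, ci = threshold_uncertainty(beta0, beta1, cov)

        probs = expit(beta0 + beta1 * self.vpd)
        # ties at exactly p = 0.5 count as positive predictions
        tpr = float(np.mean(probs[self.burned == 1] >= 0.5))
        dev_expl = 100.0 * (1.0 - fit.deviance / fit.null_deviance)
        return FireOccurrenceResults(
            stratum=self.stratum,
            params=np.array([beta0, beta1]),
            cov_params=cov,
            bse=np.asarray(fit.bse, dtype=float),
            vpd_p50=p50,
            se_p50=se,
            ci_p50=ci,
            auc=auc_val if beta1 > 0 else 1.0 - auc_val,
            tpr=tpr,
            deviance_explained=dev_expl,
            n_rows=len(self.burned),
            converged=bool(fit.converged),
        )


def fit_logistic(samples: pd.DataFrame) -> tuple[float, float]:
    """Maximum-likelihood (beta0, beta1) for a sample table; see the model class."""
    res = FireOccurrenceModel.from_dataframe(samples).fit()
    return res.beta0, res.beta1


def evaluate(results: FireOccurrenceResults, samples: pd.DataFrame) -> tuple[float, float, float]:
    """(AUC, TPR, % deviance explained) of a fitted model on labelled samples."""
    y = samples["burned"].values
    probs = np.asarray(results.predict(samples["vpd_kpa"].values))
    auc = roc_auc(y, probs)
    tpr = float(np.mean(probs[y == 1] >= 0.5))
    eps = 1e-12
    p = np.clip(probs, eps, 1 - eps)
    dev = -2.0 * np.sum(y * np.log(p) + (1 - y) * np.log1p(-p))
    pbar = np.clip(np.mean(y), eps, 1 - eps)
    null_dev = -2.0 * np.sum(y * np.log(pbar) + (1 - y) * np.log1p(-pbar))
    return auc, tpr, 100.0 * (1.0 - dev / null_dev)


def fit_all_strata(
    samples: pd.DataFrame,
    biome_groups: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, dict[str, float], list[str]]:
    """Fit one occurrence model per stratum and summarise group medians.

    Returns ``(table, medians, unfittable)`` where ``table`` has one row per
    fitted stratum (beta0, beta1, vpd_p50, se, ci, auc, tpr, dev_expl, n),
    ``medians`` maps each biome group — plus ``"overall"`` — to the median
    VPD_P50, with ``<group>_tpr`` entries for median TPR, and ``unfittable``
    names strata that could not be fitted (they are listed, never dropped
    silently).
    """
    rows = []
    unfittable: list[str] = []
    results: dict[str, FireOccurrenceResults] = {}
    for stratum, group in samples.groupby("stratum"):
        try:
            res = FireOccurrenceModel.from_dataframe(group, stratum=str(stratum)).fit()
        except UnfittableError:
            unfittable.append(str(stratum))
            continue
        results[str(stratum)] = res
        rows.append(
            {
                "stratum": str(stratum),
                "beta0": res.beta0,
                "beta1": res.beta1,
                "vpd_p50": res.vpd_p50,
                "se": res.se_p50,
                "ci_lo": res.ci_p50[0],
                "ci_hi": res.ci_p50[1],
                "auc": res.auc,
                "tpr": res.tpr,
                "dev_expl": res.deviance_explained,
                "n": res.n_rows,
                "separated": res.separated,
            }
        )
    table = pd.DataFrame(rows)
    medians: dict[str, float] = {}
    if len(table):
        medians["overall"] = float(table["vpd_p50"].median())
        medians["overall_tpr"] = float(table["tpr"].median())
        if biome_groups:
            table = table.assign(
                biome_group=[biome_groups.get(s, "") for s in table["stratum"]]
            )
            for grp, sub in table.groupby("biome_group"):
                if grp:
                    medians[str(grp)] = float(sub["vpd_p50"].median())
                    medians[f"{grp}_tpr"] = float(sub["tpr"].median())
    return table, medians, unfittable
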