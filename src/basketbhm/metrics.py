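"""Simulation performance metrics with Monte Carlo standard errors.

Given ``B`` replicate estimates ``theta_hat_k^b`` of a true effect
``theta_k``, the estimators are

* bias      = mean_b(theta_hat) - theta,      MCSE = SD / sqrt(B)
* SD        = sqrt(sum_b (theta_hat - mean)^2 / (B-1)),
              MCSE = SD / sqrt(2(B-1))
* RMSE      = sqrt(MSE),  MSE = sum_b (theta_hat - theta)^2 / B,
              MCSE = MCSE(MSE) / (2 RMSE)
* RMSE reduction of method 2 vs method 1 = (1 - RMSE2/RMSE1) x 100, with
  a delta-method MCSE built from MCSE(MSE1), MCSE(MSE2) and the
  covariance of the per-replicate squared errors (the replicates must be
  paired, i.e. share the simulated datasets)
* rejection rate, with the binomial MCSE sqrt(r(1-r)/B).

Note the denominator conventions: SD uses ``B-1`` while MSE uses ``B``,
so ``RMSE^2 = bias^2 + SD^2 (B-1)/B`` holds as an exact identity and is
verified on every report.

Trial-level rates: the family-wise error rate (FWER) is the proportion
of replicates rejecting at least one truly-null subtrial (``theta_k =
0``) and disjunctive power the proportion rejecting at least one
effective subtrial.

Replicates whose fit did not converge are excluded from the moment
metrics (with ``B`` reduced accordingly) and counted as non-rejections
in the rate metrics; the convergence rate is reported alongside.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ReplicateResults",
    "MetricReport",
    "compute_metrics",
    "nominal_fwer",
]


@dataclass(frozen=True)
class ReplicateResults:
    """Per-replicate estimates and test decisions for one method.

    ``estimates`` and ``rejections`` have shape (B, K); ``converged``
    has shape (B,).  ``seeds`` optionally records the per-replicate data
    seeds and is used to verify pairing between methods.
    """

    method: str
    estimates: np.ndarray
    rejections: np.ndarray
    theta_true: np.ndarray
    converged: np.ndarray | None = None
    seeds: np.ndarray | None = None

    def __post_init__(self):
        est = np.atleast_2d(np.asarray(self.estimates, dtype=float))
        rej = np.atleast_2d(np.asarray(self.rejections, dtype=bool))
        theta = np.asarray(self.theta_true, dtype=float)
        conv = (
            np.ones(est.shape[0], dtype=bool)
            if self.converged is None
            else np.asarray(self.converged, dtype=bool)
        )
        object.__setattr__(self, "estimates", est)
        object.__setattr__(self, "rejections", rej)
        object.__setattr__(self, "theta_true", theta)
        object.__setattr__(self, "converged", conv)
        if self.seeds is not None:
            object.__setattr__(self, "seeds", np.asarray(self.seeds))
        if est.shape != rej.shape or est.shape[1] != theta.shape[0]:
            raise ValueError("inconsistent array shapes in ReplicateResults")
        if conv.shape[0] != est.shape[0]:
            raise ValueError("converged flag length must equal B")

    @property
    def B(self) -> int:
        return self.estimates.shape[0]

    @property
    def K(self) -> int:
        return self.estimates.shape[1]


@dataclass(frozen=True)
class MetricReport:
    """Per-subtrial and trial-level performance metrics for one method."""

    method: str
    per_subtrial: pd.DataFrame
    fwer: float
    fwer_mcse: float
    disjunctive_power: float
    disjunctive_power_mcse: float
    convergence_rate: float
    B: int
    B_moments: int
    reference_method: str | None = None

    def to_tidy(self) -> pd.DataFrame:
        """Long-format table (method, subtrial, metric, estimate, mcse)."""
        rows = []
        for _, r in self.per_subtrial.iterrows():
            for metric in ("bias", "sd", "rmse", "rmse_reduction", "rejection_rate"):
                if np.isnan(r[metric]) and metric == "rmse_reduction":
                    continue
                rows.append(
                    {
                        "method": self.method,
                        "subtrial": int(r["subtrial"]),
                        "metric": metric,
                        "estimate": r[metric],
                        "mcse": r[f"{metric}_mcse"],
                    }
                )
        for metric, val, mcse in (
            ("fwer", self.fwer, self.fwer_mcse),
            ("disjunctive_power", self.disjunctive_power, self.disjunctive_power_mcse),
            ("convergence_rate", self.convergence_rate, np.nan),
        ):
            rows.append(
                {"method": self.method, "subtrial": 0, "metric": metric,
                 "estimate": val, "mcse": mcse}
            )
        return pd.DataFrame(rows)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "method": self.method,
            "reference_method": self.reference_method,
            "B": self.B,
            "B_moments": self.B_moments,
            "fwer": _none_if_nan(self.fwer),
            "fwer_mcse": _none_if_nan(self.fwer_mcse),
            "disjunctive_power": _none_if_nan(self.disjunctive_power),
            "disjunctive_power_mcse": _none_if_nan(self.disjunctive_power_mcse),
            "convergence_rate": self.convergence_rate,
            "per_subtrial": json.loads(self.per_subtrial.to_json(orient="records")),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def format_table(self) -> str:
        """Fixed-width text table in the style of a results table."""
        cols = ["subtrial", "bias", "sd", "rmse", "rmse_reduction", "rejection_rate"]
        out = [f"method: {self.method} (B={self.B}, convergence {self.convergence_rate:.3f})"]
        header = "".join(f"{c:>16}" for c in cols)
        out.append(header)
        for _, r in self.per_subtrial.iterrows():
            cells = [f"{int(r['subtrial']):>16d}"]
            for c in cols[1:]:
                if np.isnan(r[c]):
                    cells.append(f"{'—':>16}")
                else:
                    cells.append(f"{r[c]:>8.3f} ({r[c + '_mcse']:.3f})".rjust(16))
            out.append("".join(cells))
        return "\n".join(out)


def _none_if_nan(x):
    return None if (x is None or (isinstance(x, float) and np.isnan(x))) else x


def nominal_fwer(alpha: float, m: int) -> float:
    """Nominal family-wise error rate for m independent tests at level alpha:
    ``1 - (1 - alpha)^m``."""
    if not 0 <= alpha < 1:
        raise ValueError("alpha must be in [0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return 1.0 - (1.0 - alpha) ** m


def _moment_metrics(est: np.ndarray, theta: float):
    """Bias/SD/RMSE and their MCSEs for one subtrial's replicate estimates."""
    B = est.shape[0]
    mean = est.mean()
    bias = mean - theta
    centered = est - mean
    ss = centered @ centered
    sd = np.sqrt(ss / (B - 1))
    bias_mcse = np.sqrt(ss / (B * (B - 1)))
    sd_mcse = sd / np.sqrt(2.0 * (B - 1))
    sq = (est - theta) ** 2
    mse = sq.mean()
    rmse = np.sqrt(mse)
    mse_mcse = np.sqrt(((sq - mse) ** 2).sum() / (B * (B - 1)))
    rmse_mcse = mse_mcse / (2.0 * rmse) if rmse > 0 else 0.0
    return bias, bias_mcse, sd, sd_mcse, rmse, rmse_mcse, mse, mse_mcse, sq


def compute_metrics(
    results: ReplicateResults, reference: ReplicateResults | None = None
) -> MetricReport:
    """Compute the full metric set, against ``reference`` for RMSE reduction.

    The reference must be paired: same number of replicates and (when
    seeds are recorded on both) identical per-replicate data seeds, so
    the covariance term of the RMSE-ratio MCSE is estimable.
    """
    if reference is not None:
        if reference.B != results.B:
            raise ValueError("reference has a different number of replicates")
        if (
            results.seeds is not None
            and reference.seeds is not None
            and not np.array_equal(results.seeds, reference.seeds)
        ):
            raise ValueError("reference replicates are not paired (seeds differ)")

    theta = results.theta_true
    conv = results.converged
    conv_pair = conv if reference is None else (conv & reference.converged)

    rows = []
    for k in range(results.K):
        est = results.estimates[conv, k]
        B_m = est.shape[0]
        if B_m < 2:
            raise ValueError("need at least 2 converged replicates for moment metrics")
        (bias, bias_mcse, sd, sd_mcse, rmse, rmse_mcse,
         mse, mse_mcse, _) = _moment_metrics(est, theta[k])
        # exact identity linking the two denominator conventions
        if abs(rmse**2 - (bias**2 + sd**2 * (B_m - 1) / B_m)) > 1e-10 * max(rmse**2, 1.0):
            raise AssertionError("RMSE^2 != bias^2 + SD^2 (B-1)/B")

        red = red_mcse = np.nan
        if reference is not None:
            est2 = results.estimates[conv_pair, k]
            est1 = reference.estimates[conv_pair, k]
            Bp = est1.shape[0]
            sq2 = (est2 - theta[k]) ** 2
            sq1 = (est1 - theta[k]) ** 2
            mse2, mse1 = sq2.mean(), sq1.mean()
            if mse1 <= 0:
                raise ValueError("reference MSE is zero; RMSE reduction undefined")
            mcse_mse2 = np.sqrt(((sq2 - mse2) ** 2).sum() / (Bp * (Bp - 1)))
            mcse_mse1 = np.sqrt(((sq1 - mse1) ** 2).sum() / (Bp * (Bp - 1)))
            cov12 = ((sq1 - mse1) @ (sq2 - mse2)) / (Bp - 1) / Bp
            var_ratio = (
                mcse_mse2**2 / mse1**2
                + mse2**2 * mcse_mse1**2 / mse1**4
                - 2.0 * mse2 * cov12 / mse1**3
            )
            # guard cancellation: identical paired methods give exactly 0
            scale = mcse_mse2**2 / mse1**2 + mse2**2 * mcse_mse1**2 / mse1**4
            if var_ratio < 1e-12 * scale:
                var_ratio = 0.0
            mcse_ratio = np.sqrt(max(var_ratio, 0.0))
            red = (1.0 - np.sqrt(mse2 / mse1)) * 100.0
            red_mcse = mcse_ratio * np.sqrt(mse1 / mse2) * 50.0 if mse2 > 0 else 0.0

        # rates use the full B with nonconverged replicates as non-rejections
        rej = results.rejections[:, k] & conv
        rate = rej.mean()
        rate_mcse = np.sqrt(rate * (1.0 - rate) / results.B)
        rows.append(
            {
                "subtrial": k + 1,
                "bias": bias, "bias_mcse": bias_mcse,
                "sd": sd, "sd_mcse": sd_mcse,
                "rmse": rmse, "rmse_mcse": rmse_mcse,
                "rmse_reduction": red, "rmse_reduction_mcse": red_mcse,
                "rejection_rate": rate, "rejection_rate_mcse": rate_mcse,
            }
        )

    null_mask = theta == 0.0
    eff_mask = ~null_mask
    rej_all = results.rejections & conv[:, None]
    if null_mask.any():
        fwer_ind = rej_all[:, null_mask].any(axis=1)
        fwer = fwer_ind.mean()
        fwer_mcse = np.sqrt(fwer * (1 - fwer) / results.B)
    else:
        fwer, fwer_mcse = np.nan, np.nan
    if eff_mask.any():
        pow_ind = rej_all[:, eff_mask].any(axis=1)
        power = pow_ind.mean()
        power_mcse = np.sqrt(power * (1 - power) / results.B)
    else:
        power, power_mcse = np.nan, np.nan

    return MetricReport(
        method=results.method,
        per_subtrial=pd.DataFrame(rows),
        fwer=float(fwer),
        fwer_mcse=float(fwer_mcse),
        disjunctive_power=float(power),
        disjunctive_power_mcse=float(power_mcse),
        convergence_rate=float(conv.mean()),
        B=results.B,
        B_moments=int(conv.sum()),
        reference_method=None if reference is None else reference.method,
    )
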