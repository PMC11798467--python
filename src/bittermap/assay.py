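"""Receptor functional-assay analytics.

Luminescence responses are summarised per well as the area under the
curve (AUC, in relative light units).  A substance is called an agonist
of a receptor when its replicate responses are significantly different
from the receptor's own buffer wells (two-sided Welch's t-test,
Benjamini–Hochberg correction across the substances tested on that
receptor, alpha = 0.05).  Significant responses are normalised to the
relative activity

    (response_chemical - response_buffer) / (response_max - response_buffer)

using replicate means, where ``response_max`` is the strongest
substance response of that receptor (so the strongest agonist scores 1).
Dose–response series are screened with one-sided Dunnett many-to-one
comparisons against the lowest concentration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AssayPlate",
    "AgonistCall",
    "auc_response",
    "call_agonists",
    "relative_activity_matrix",
    "dose_response_flags",
    "dunnett_critical_value",
    "BUFFER",
]

BUFFER = "buffer"


@dataclass
class AssayPlate:
    """Long-format plate: one row per well with columns ``receptor``,
    ``substance``, ``response`` (and optionally ``concentration``).

    The reserved substance ``buffer`` must be present for every
    receptor.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"receptor", "substance", "response"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"plate table lacks columns {sorted(missing)}")
        for receptor, sub in self.data.groupby("receptor"):
            if BUFFER not in set(sub["substance"]):
                raise ValueError(f"receptor {receptor!r} has no buffer wells")

    @classmethod
    def from_tsv(cls, path) -> "AssayPlate":
        return cls(pd.read_csv(path, sep="\t", comment="#"))

    def receptors(self) -> list[str]:
        return sorted(self.data["receptor"].unique())

    def responses(self, receptor: str, substance: str) -> np.ndarray:
        mask = (self.data["receptor"] == receptor) & \
               (self.data["substance"] == substance)
        return self.data.loc[mask, "response"].to_numpy(dtype=float)


@dataclass
class AgonistCall:
    receptor: str
    substance: str
    mean_diff: float
    p_raw: float
    p_bh: float
    significant: bool
    relative_activity: float | None = None


def auc_response(luminescence, timestamps) -> float:
    """Trapezoidal area under a luminescence time series (RLU)."""
    y = np.asarray(luminescence, dtype=float)
    t = np.asarray(timestamps, dtype=float)
    if len(t) < 2:
        raise ValueError("need at least two time points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    return float(np.trapezoid(y, t))


def call_agonists(plate: AssayPlate, alpha: float = 0.05,
                  family: str = "receptor") -> list[AgonistCall]:
    """Agonist calls for every (receptor, substance) pair on the plate.

    Each substance is compared against the pooled buffer wells of the
    same receptor with a two-sided Welch t-test; p-values are BH-
    adjusted within the receptor's substance family (or across the whole
    plate with ``family="global"``).  The relative activity is computed
    for significant substances only, normalised to the receptor's
    strongest substance response.
    """
    if family not in ("receptor", "global"):
        raise ValueError("family must be 'receptor' or 'global'")
    per_receptor: list[tuple[str, list[str], list[float], list[float], float]] = []
    for receptor in plate.receptors():
        buffer = plate.responses(receptor, BUFFER)
        substances = sorted(
            s for s in plate.data.loc[plate.data["receptor"] == receptor,
                                      "substance"].unique()
            if s != BUFFER
        )
        if not substances:
            continue
        p_raw = []
        diffs = []
        for substance in substances:
            resp = plate.responses(receptor, substance)
            if np.var(resp) == 0 and np.var(buffer) == 0:
                raise ValueError(
                    f"zero variance in both groups for {receptor}/{substance}")
            res = stats.ttest_ind(resp, buffer, equal_var=False)
            p_raw.append(float(res.pvalue))
            diffs.append(float(np.mean(resp) - np.mean(buffer)))
        max_response = max(
            float(np.mean(plate.responses(receptor, s))) for s in substances
        )
        per_receptor.append((receptor, substances, p_raw, diffs,
                             max_response - float(np.mean(buffer))))

    if family == "global":
        pooled = [p for _, _, p_raw, _, _ in per_receptor for p in p_raw]
        adjusted = list(stats.false_discovery_control(pooled, method="bh"))
        p_bh_groups = []
        for _, substances, _, _, _ in per_receptor:
            p_bh_groups.append([adjusted.pop(0) for _ in substances])
    else:
        p_bh_groups = [
            list(stats.false_discovery_control(p_raw, method="bh"))
            for _, _, p_raw, _, _ in per_receptor
        ]

    calls: list[AgonistCall] = []
    for (receptor, substances, p_raw, diffs, denom), p_bh in zip(per_receptor,
                                                                 p_bh_groups):
        for substance, diff, pr, pb in zip(substances, diffs, p_raw, p_bh):
            significant = bool(pb < alpha)
            rel = None
            if significant:
                if denom == 0:
                    raise ValueError(
                        f"receptor {receptor!r}: max response equals buffer")
                rel = diff / denom
            calls.append(AgonistCall(
                receptor=receptor, substance=substance, mean_diff=diff,
                p_raw=pr, p_bh=float(pb), significant=significant,
                relative_activity=rel,
            ))
    return calls


def relative_activity_matrix(calls: list[AgonistCall]) -> pd.DataFrame:
    """Receptor x substance matrix of relative activities.

    Non-significant entries are NaN (rendered blank downstream); the
    strongest agonist of each receptor scores 1.  Affine-invariant:
    adding a constant to all of a receptor's responses leaves the
    matrix unchanged.
    """
    receptors = sorted({c.receptor for c in calls})
    substances = sorted({c.substance for c in calls})
    out = pd.DataFrame(np.nan, index=receptors, columns=substances)
    for c in calls:
        if c.significant:
            out.loc[c.receptor, c.substance] = c.relative_activity
    return out


# ---------------------------------------------------------------------------
# Dose–response (Dunnett many-to-one)

def dunnett_critical_value(k: int, df: int, alpha: float = 0.05,
                           rho: float = 0.5) -> float:
    """One-sided Dunnett critical value for ``k`` comparisons against a
    common control, ``df`` error degrees of freedom, correlation ``rho``
    (0.5 for a balanced design).

    Computed by numerical quadrature over the equicorrelated
    multivariate-t representation
    ``P(max_i T_i <= c) = E_{S, Z0}[ Phi((c*S - sqrt(rho)*Z0)/sqrt(1-rho))^k ]``
    with ``S ~ sqrt(chi2_df / df)`` and ``Z0 ~ N(0, 1)``.
    """
    from scipy.optimize import brentq

    z, wz = np.polynomial.hermite_e.hermegauss(80)
    wz = wz / wz.sum()
    qs = (np.arange(1, 257) - 0.5) / 256.0
    s = np.sqrt(stats.chi2.ppf(qs, df) / df)

    def coverage(c: float) -> float:
        inner = stats.norm.cdf(
            (c * s[:, None] - math.sqrt(rho) * z[None, :])
            / math.sqrt(1.0 - rho)
        ) ** k
        return float(np.mean(inner @ wz))

    return float(brentq(lambda c: coverage(c) - (1.0 - alpha), 0.5, 10.0,
                        xtol=1e-6))


def dose_response_flags(series: dict[float, list[float]],
                        alpha: float = 0.05, seed: int = 0) -> float | None:
    """Smallest concentration with a significantly elevated response.

    ``series`` maps concentration to replicate responses.  The lowest
    concentration is the control; the others are compared with one-sided
    (greater) Dunnett many-to-one tests at family-wise level ``alpha``.
    Returns the minimal significant concentration, or ``None``.
    """
    concentrations = sorted(series)
    if len(concentrations) < 2:
        raise ValueError("need at least two concentrations")
    control = np.asarray(series[concentrations[0]], dtype=float)
    samples = [np.asarray(series[c], dtype=float) for c in concentrations[1:]]
    res = stats.dunnett(*samples, control=control, alternative="greater",
                        random_state=np.random.default_rng(seed))
    for conc, p in zip(concentrations[1:], res.pvalue):
        if p < alpha:
            return conc
    return None
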