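"""False-positive report probability (FPRP) analysis.

For each significant finding, FPRP combines the observed two-sided p-value
(alpha), the power of the test to detect a prespecified odds ratio OR0, and a
prior probability pi that the association is real:

    FPRP = alpha * (1 - pi) / (alpha * (1 - pi) + power * pi)

Power uses the normal (Wald) approximation on the log-OR scale: if the log-OR
estimator is Normal(ln OR0, se^2), the two-sided level-alpha test rejects with
probability Phi(|ln OR0|/se - z) + Phi(-|ln OR0|/se - z), z = z_{1-alpha/2}.

Defaults follow common practice for protective candidate-SNP findings:
OR0 = 0.67, headline prior 0.1 within the grid
{0.25, 0.1, 0.01, 0.001, 0.0001}, noteworthiness threshold FPRP < 0.2.
For risk findings (OR > 1) the detection target is reciprocated to 1/OR0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .stats import Z95, AssociationResult

log = logging.getLogger(__name__)

DEFAULT_PRIORS = (0.25, 0.1, 0.01, 0.001, 0.0001)
DEFAULT_OR0 = 0.67
DEFAULT_THRESHOLD = 0.2


@dataclass
class FprpRow:
    """FPRP across the prior grid for one significant finding."""

    label: str
    or_estimate: float
    ci_low: float
    ci_high: float
    alpha: float
    power: float
    or0: float
    priors: tuple
    fprp_values: dict = field(default_factory=dict)
    noteworthy: dict = field(default_factory=dict)


def se_log_or(cells=None, ci=None) -> float:
    """SE of the log odds ratio, from 2x2 cell counts or from a 95% CI.

    From counts: sqrt(sum of reciprocal cells). From a Wald CI (lo, hi):
    (ln hi - ln lo) / (2 * 1.959964).
    """
    if (cells is None) == (ci is None):
        raise ValueError("provide exactly one of cells or ci")
    if cells is not None:
        cells = [float(c) for c in cells]
        if len(cells) != 4 or min(cells) <= 0:
            raise ValueError("need four positive cell counts")
        return float(np.sqrt(sum(1.0 / c for c in cells)))
    lo, hi = float(ci[0]), float(ci[1])
    if not 0 < lo < hi:
        raise ValueError(f"invalid CI ({lo}, {hi}): need 0 < low < high")
    return float((np.log(hi) - np.log(lo)) / (2 * Z95))


def statistical_power(se: float, alpha: float, or0: float = DEFAULT_OR0) -> float:
    """Probability a two-sided level-``alpha`` Wald test rejects when the true
    odds ratio is ``or0`` and the log-OR estimator has standard error ``se``."""
    if se <= 0:
        raise ValueError("se must be positive")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if or0 <= 0 or or0 == 1:
        raise ValueError("or0 must be positive and different from 1")
    z = sps.norm.isf(alpha / 2)
    shift = abs(np.log(or0)) / se
    return float(sps.norm.cdf(shift - z) + sps.norm.cdf(-shift - z))


def fprp_value(alpha: float, power: float, prior: float) -> float:
    """FPRP for one (observed p, power, prior) triple."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if not 0 < power <= 1:
        raise ValueError("power must be in (0, 1]")
    if not 0 <= prior <= 1:
        raise ValueError("prior must be in [0, 1]")
    if prior == 1:
        return 0.0
    if prior == 0:
        return 1.0
    num = alpha * (1 - prior)
    return float(num / (num + power * prior))


def fprp_row(
    label: str,
    or_estimate: float,
    ci: tuple[float, float],
    alpha: float,
    *,
    cells=None,
    priors=DEFAULT_PRIORS,
    or0: float = DEFAULT_OR0,
    threshold: float = DEFAULT_THRESHOLD,
) -> FprpRow:
    """Evaluate power and the FPRP grid for one finding.

    The log-OR standard error comes from ``cells`` when supplied (four
    positive counts), otherwise from the CI width. For a risk finding
    (OR > 1) a protective ``or0`` is reciprocated so the detection target
    sits on the same side as the estimate.
    """
    if cells is not None and min(float(c) for c in cells) > 0:
        se = se_log_or(cells=cells)
    else:
        se = se_log_or(ci=ci)
    target = or0
    if or_estimate > 1 and or0 < 1:
        target = 1.0 / or0
    power = statistical_power(se, alpha, target)
    values = {pi: fprp_value(alpha, power, pi) for pi in priors}
    return FprpRow(
        label=label,
        or_estimate=or_estimate,
        ci_low=ci[0],
        ci_high=ci[1],
        alpha=alpha,
        power=power,
        or0=target,
        priors=tuple(priors),
        fprp_values=values,
        noteworthy={pi: v < threshold for pi, v in values.items()},
    )


def fprp_table(
    findings,
    priors=DEFAULT_PRIORS,
    or0: float = DEFAULT_OR0,
    threshold: float = DEFAULT_THRESHOLD,
    significance_gate: float = 0.05,
) -> list[FprpRow]:
    """FPRP rows for a list of findings, in input order.

    ``findings`` may be :class:`~snpcc.stats.AssociationResult` objects or
    ``(label, or, ci_low, ci_high, p)`` tuples. Non-estimable findings and
    those with p at or above the significance gate are skipped with a log
    entry, mirroring the convention of running FPRP only on significant
    results.
    """
    rows: list[FprpRow] = []
    for finding in findings:
        if isinstance(finding, AssociationResult):
            if not finding.estimable:
                log.info("FPRP: skipping non-estimable finding %s", finding.label)
                continue
            label = finding.label
            orr, lo, hi, p = (finding.or_estimate, finding.ci_low,
                              finding.ci_high, finding.p_value)
            cells = None
            c = finding.cells
            if set(c) == {"n_case_exposed", "n_case_ref", "n_ctrl_exposed", "n_ctrl_ref"}:
                cells = [c["n_case_exposed"], c["n_case_ref"],
                         c["n_ctrl_exposed"], c["n_ctrl_ref"]]
                if min(cells) <= 0:
                    cells = None
        else:
            label, orr, lo, hi, p = finding
            cells = None
        if not p < significance_gate:
            log.info("FPRP: skipping %s (p=%.3g >= gate %.3g)", label, p, significance_gate)
            continue
        rows.append(
            fprp_row(label, orr, (lo, hi), p, cells=cells,
                     priors=priors, or0=or0, threshold=threshold)
        )
    return rows


__all__ = [
    "FprpRow", "se_log_or", "statistical_power", "fprp_value", "fprp_row",
    "fprp_table", "DEFAULT_PRIORS", "DEFAULT_OR0", "DEFAULT_THRESHOLD",
]
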