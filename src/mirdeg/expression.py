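"""Two-library miRNA expression: RPM normalization, log2 fold changes,
an exact count-difference significance test, regulation calls, and the
2^-ddCt qPCR arithmetic.

The study design has one library per condition, so significance uses the
Audic–Claverie exact test for a tag-count difference between two libraries
of known sizes (a Fisher-exact option is provided); no dispersion
modelling is attempted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import fisher_exact

CALLS = ("specific_wild", "specific_mutant", "up_in_mutant",
         "down_in_mutant", "unchanged")


@dataclass
class DEConfig:
    """Differential-call thresholds.

    fc_threshold: |log2(wild/mutant)| must exceed this (default 1, i.e. 2x);
    alpha: significance level on the (optionally adjusted) p-value;
    pseudo_count: raw-read pseudo-count applied only when a zero is present;
    specific_min_reads: reads required in one library (vs 0 in the other)
        to call a miRNA specifically expressed;
    adjust: "none" or "BH" (Benjamini–Hochberg).
    """

    fc_threshold: float = 1.0
    alpha: float = 0.05
    pseudo_count: float = 1.0
    specific_min_reads: float = 10.0
    adjust: str = "none"
    test: str = "ac"  # "ac" | "fisher"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.fc_threshold <= 0 or self.pseudo_count <= 0:
            raise ValueError("thresholds must be positive")


def rpm_normalize(count: float, clean_total: float) -> float:
    """Reads-per-million: count / clean-library total x 10^6."""
    if clean_total <= 0:
        raise ValueError("clean_total must be > 0")
    return count / clean_total * 1e6


def log2_fold_change(rpm_wild: float, rpm_mutant: float,
                     pseudo_rpm: float = 0.0) -> float:
    """log2(wild/mutant) with pseudo-stabilization.

    ``pseudo_rpm`` (the RPM equivalent of the raw pseudo-count) is added to
    both sides only when either side is zero; if both are zero the fold
    change is undefined (NaN) and the record is excluded from DE calls.
    """
    if rpm_wild == 0 and rpm_mutant == 0:
        return float("nan")
    if rpm_wild == 0 or rpm_mutant == 0:
        rpm_wild += pseudo_rpm
        rpm_mutant += pseudo_rpm
    return math.log2(rpm_wild / rpm_mutant)


def _ac_log_pmf(y: np.ndarray, x: int, log_r: float) -> np.ndarray:
    """log p(y|x) = y log r + log (x+y)! - log x! - log y! - (x+y+1) log(1+r)."""
    y = np.asarray(y, dtype=float)
    log1pr = np.log1p(np.exp(log_r)) if log_r < 50 else log_r
    return (y * log_r + gammaln(x + y + 1) - gammaln(x + 1) - gammaln(y + 1)
            - (x + y + 1) * log1pr)


def ac_test(x: int, y: int, Nx: float, Ny: float) -> float:
    """Two-sided Audic–Claverie p-value for counts x, y in libraries Nx, Ny.

    Under the model p(y|x) = (Ny/Nx)^y (x+y)! / (x! y! (1+Ny/Nx)^(x+y+1)),
    the two-sided p is min(1, 2 min(P(Y <= y), P(Y >= y))), computed in log
    space (overflow-safe by construction).
    """
    if Nx <= 0 or Ny <= 0:
        raise ValueError("library totals must be > 0")
    if x < 0 or y < 0 or x != int(x) or y != int(y):
        raise ValueError("counts must be nonnegative integers")
    x, y = int(x), int(y)
    log_r = math.log(Ny) - math.log(Nx)
    # lower tail P(Y <= y) by direct log-space summation
    p_le = float(np.exp(logsumexp(_ac_log_pmf(np.arange(y + 1), x, log_r))))
    if y == 0:
        p_ge = 1.0
    else:
        p_lt = float(np.exp(logsumexp(_ac_log_pmf(np.arange(y), x, log_r))))
        p_ge = max(0.0, 1.0 - p_lt)
    return min(1.0, 2.0 * min(p_le, p_ge))


def fisher_test(x: int, y: int, Nx: float, Ny: float) -> float:
    """Fisher-exact alternative on the 2x2 table of counts vs remainders."""
    table = [[x, y], [int(round(Nx)) - x, int(round(Ny)) - y]]
    return float(fisher_exact(table, alternative="two-sided")[1])


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n - 1, -1, -1):
        idx = order[rank]
        running = min(running, p[idx] * n / (rank + 1))
        adj[idx] = running
    return adj


def build_expression_table(counts_wild: dict[str, float], counts_mutant: dict[str, float],
                           total_wild: float, total_mutant: float,
                           cfg: Optional[DEConfig] = None) -> pd.DataFrame:
    """Per-miRNA expression records for the two libraries.

    Columns: count_wild, count_mutant, rpm_wild, rpm_mutant, log2_fc,
    p_value, call, degradome_evidenced (False until flagged by the caller).
    """
    cfg = cfg or DEConfig()
    ids = sorted(set(counts_wild) | set(counts_mutant))
    rows = []
    test = ac_test if cfg.test == "ac" else fisher_test
    for mid in ids:
        cw = counts_wild.get(mid, 0)
        cm = counts_mutant.get(mid, 0)
        rw = rpm_normalize(cw, total_wild)
        rm = rpm_normalize(cm, total_mutant)
        if cw == 0 or cm == 0:
            fc = _pseudo_fc(cw, cm, total_wild, total_mutant, cfg)
        else:
            fc = log2_fold_change(rw, rm)
        p = test(int(round(cw)), int(round(cm)), total_wild, total_mutant)
        rows.append((mid, cw, cm, rw, rm, fc, p))
    df = pd.DataFrame(rows, columns=["mirna_id", "count_wild", "count_mutant",
                                     "rpm_wild", "rpm_mutant", "log2_fc", "p_value"])
    if cfg.adjust == "BH" and len(df):
        df["p_value"] = bh_adjust(df["p_value"].to_numpy())
    df["degradome_evidenced"] = False
    return call_sets(df, cfg)


def _pseudo_fc(cw: float, cm: float, tw: float, tm: float, cfg: DEConfig) -> float:
    """Fold change with the raw pseudo-count applied before normalization."""
    if cw == 0 and cm == 0:
        return float("nan")
    cw2 = cw + cfg.pseudo_count
    cm2 = cm + cfg.pseudo_count
    return math.log2(rpm_normalize(cw2, tw) / rpm_normalize(cm2, tm))


def call_sets(records: pd.DataFrame, cfg: Optional[DEConfig] = None) -> pd.DataFrame:
    """Assign each record exactly one of the five regulation calls.

    specific_X: >= specific_min_reads raw reads in X and 0 in the other;
    otherwise up/down in the mutant when |log2 FC| > fc_threshold and
    p < alpha (direction by the sign of the wild/mutant ratio); otherwise
    unchanged. Records with undefined fold change are unchanged.
    """
    cfg = cfg or DEConfig()
    calls = []
    for rec in records.itertuples():
        cw, cm = rec.count_wild, rec.count_mutant
        if cw >= cfg.specific_min_reads and cm == 0:
            calls.append("specific_wild")
        elif cm >= cfg.specific_min_reads and cw == 0:
            calls.append("specific_mutant")
        elif (not math.isnan(rec.log2_fc) and abs(rec.log2_fc) > cfg.fc_threshold
              and rec.p_value < cfg.alpha):
            calls.append("down_in_mutant" if rec.log2_fc > 0 else "up_in_mutant")
        else:
            calls.append("unchanged")
    out = records.copy()
    out["call"] = calls
    return out


def ddct(ct_target_sample: float, ct_ref_sample: float,
         ct_target_calibrator: float, ct_ref_calibrator: float) -> float:
    """Relative qPCR expression by the 2^-ddCt method.

    2^-((Ct_target,sample - Ct_ref,sample) - (Ct_target,cal - Ct_ref,cal)).
    """
    delta_sample = ct_target_sample - ct_ref_sample
    delta_cal = ct_target_calibrator - ct_ref_calibrator
    return 2.0 ** (-(delta_sample - delta_cal))
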