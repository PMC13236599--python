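"""Mendelian segregation, genotype-phenotype linkage, penetrance and qPCR.

Hemizygous EVE loci transmit to half of haploid meiotic progeny; symptoms are
expected to co-segregate with the active element.  Linkage is tested with a
2x2 chi-square (optional Yates continuity correction, the default of the
statistical environment the field uses), segregation against arbitrary
expected ratios with a goodness-of-fit chi-square.  Penetrance — the
probability that a carrier of the active element expresses symptoms — is our
modelling addition reconciling observed symptomatic fractions below the
all-carriers expectation; it is estimated with a Wilson score interval.
Relative viral copy number follows the qPCR delta-Cq rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint


@dataclass
class LinkageResult:
    table: np.ndarray  # 2x2: rows EVE present/absent, cols symptomatic/asymptomatic
    chi2: float
    df: int
    p: float
    correction: bool


@dataclass
class SegregationResult:
    observed: np.ndarray
    expected: np.ndarray
    chi2: float
    df: int
    p: float


@dataclass
class PenetranceEstimate:
    estimate: float
    ci_low: float
    ci_high: float
    n_carriers: int
    n_symptomatic: int


def linkage_test(table: Sequence[Sequence[int]], correction: bool = True) -> LinkageResult:
    """2x2 chi-square test of association between an EVE and symptoms."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("table must be a 2x2 array of non-negative integers")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("all margins must be positive for a chi-square test")
    chi2, p, df, _ = stats.chi2_contingency(t, correction=correction)
    return LinkageResult(t.astype(int), float(chi2), int(df), float(p), correction)


def mendelian_test(
    counts: Sequence[int], ratio: Sequence[float] | None = None
) -> SegregationResult:
    """Goodness-of-fit chi-square of class counts against an expected ratio
    (default 1:1:...:1)."""
    obs = np.asarray(counts, dtype=float)
    if ratio is None:
        ratio = np.ones_like(obs)
    ratio = np.asarray(ratio, dtype=float)
    if len(ratio) != len(obs):
        raise ValueError("ratio and counts must have the same length")
    if (ratio <= 0).any():
        raise ValueError("expected ratio must be positive")
    expected = ratio / ratio.sum() * obs.sum()
    chi2, p = stats.chisquare(obs, expected)
    return SegregationResult(obs, expected, float(chi2), len(obs) - 1, float(p))


def combination_frequencies(
    loci: Sequence[str],
    exclusive_pairs: Sequence[tuple[str, str]] = (),
) -> dict[tuple[str, ...], float]:
    """Expected genotype-class probabilities for hemizygous loci.

    Unlinked loci each transmit with probability 1/2; homologue-exclusive
    pairs (two elements on opposite homologs of one chromosome) contribute
    exactly one of their two members, each with probability 1/2.  The returned
    mapping (tuple of present loci -> probability) sums to 1.
    """
    paired = [l for pair in exclusive_pairs for l in pair]
    if len(set(paired)) != len(paired):
        raise ValueError("a locus may appear in at most one exclusivity pair")
    unknown = set(paired) - set(loci)
    if unknown:
        raise ValueError(f"exclusive pair members not declared: {sorted(unknown)}")
    singles = [l for l in loci if l not in paired]
    out: dict[tuple[str, ...], float] = {}
    single_states = list(product([False, True], repeat=len(singles)))
    pair_states = list(product(*[(pair[0], pair[1]) for pair in exclusive_pairs]))
    for s_state in single_states:
        for p_state in pair_states:
            present = tuple(
                sorted(
                    [l for l, on in zip(singles, s_state) if on] + list(p_state)
                )
            )
            prob = (0.5 ** len(singles)) * (0.5 ** len(exclusive_pairs))
            out[present] = out.get(present, 0.0) + prob
    return out


def estimate_penetrance(
    table: pd.DataFrame, active_locus: str, alpha: float = 0.05
) -> PenetranceEstimate:
    """Symptomatic fraction among carriers of the active locus, with a Wilson
    score interval."""
    carriers = table[table[active_locus] == "present"]
    if len(carriers) == 0:
        raise ValueError(f"no carriers of {active_locus!r} in the table")
    k = int((carriers["phenotype"] == "symptomatic").sum())
    n = len(carriers)
    lo, hi = proportion_confint(k, n, alpha=alpha, method="wilson")
    return PenetranceEstimate(k / n, float(lo), float(hi), n, k)


def linkage_table(table: pd.DataFrame, locus: str) -> np.ndarray:
    """2x2 counts (locus present/absent x symptomatic/asymptomatic) from a
    progeny table."""
    present = table[locus] == "present"
    sympt = table["phenotype"] == "symptomatic"
    return np.array(
        [
            [int((present & sympt).sum()), int((present & ~sympt).sum())],
            [int((~present & sympt).sum()), int((~present & ~sympt).sum())],
        ]
    )


def relative_copy_number(cq_target: float, cq_reference: float) -> float:
    """qPCR relative copy number: 2 ** (Cq_reference - Cq_target)."""
    if not (np.isfinite(cq_target) and np.isfinite(cq_reference)):
        raise ValueError("Cq values must be finite")
    return float(2.0 ** (cq_reference - cq_target))
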