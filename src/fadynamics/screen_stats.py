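"""Signed two-sample KS statistics and hit calling for the three-condition screen.

The screen compares focal-adhesion size distributions with a two-sample
Kolmogorov–Smirnov test.  Because adhesion counts per condition run into
the tens of thousands, p-values routinely fall far below the smallest
positive double (the strongest shifts reach ~1e-277), so all p-values are
carried in the log10 domain.

The D-statistic is *signed*: its magnitude is the classical two-sample D,
and its sign is taken from the ECDF difference ``F_ref - F_test`` at the
argmax, so that a positive value means the test sample is shifted towards
larger adhesions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "KSResult",
    "HitThresholds",
    "HitCall",
    "ScreenSummary",
    "signed_ks_test",
    "log10_kolmogorov_sf",
    "classify_gene",
    "summarize_screen",
]


@dataclass(frozen=True)
class KSResult:
    """Outcome of a signed two-sample KS comparison.

    Attributes
    ----------
    signed_d : float
        Signed D-statistic in [-1, 1]; positive when the test sample is
        shifted towards larger values than the reference.
    log10_p : float
        log10 of the two-sided asymptotic p-value (<= 0).
    score : int
        -1, 0 or +1: direction of a significant shift at ``alpha``,
        0 when not significant.
    n_test, n_ref : int
        Sample sizes.
    """

    signed_d: float
    log10_p: float
    score: int
    n_test: int
    n_ref: int


@dataclass(frozen=True)
class HitThresholds:
    """Screen hit-calling thresholds.

    The increase/decrease thresholds are the stringent screen-wide cuts
    (D > 0.1 with p < 1e-40 for enlargement; D < -0.075 with p < 1e-25
    for shrinkage).  ``d_nochange``/``log10p_nochange`` quantify "no
    significant change" for the assembly/disassembly-blocked categories;
    they are a package convention and are reported with every run.
    """

    d_increase: float = 0.1
    log10p_increase: float = -40.0
    d_decrease: float = -0.075
    log10p_decrease: float = -25.0
    d_nochange: float = 0.05
    log10p_nochange: float = -10.0
    alpha_score: float = 0.05

    def __post_init__(self) -> None:
        if not (self.d_increase > 0 > self.d_decrease):
            raise ValueError("require d_increase > 0 > d_decrease")


CATEGORIES = ("increase", "decrease", "assembly_blocked", "disassembly_blocked", "none")


@dataclass
class HitCall:
    """Per-gene classification across the three screen comparisons."""

    gene: str
    ks_dmso_vs_control: KSResult
    ks_noco_vs_dmso: KSResult
    ks_washout_vs_noco: KSResult
    category: str = "none"
    deselected: bool = False


@dataclass
class ScreenSummary:
    counts: dict[str, int] = field(default_factory=dict)
    deselected: list[str] = field(default_factory=list)
    total_hits: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def _log10_kolmogorov_sf_large(lam: float) -> float:
    # Alternating series Q(lam) = 2 sum_k (-1)^(k-1) exp(-2 k^2 lam^2),
    # evaluated with the leading term factored out so that lam ~ 20
    # (p ~ 1e-350) stays representable.
    s = 0.0
    for k in range(2, 12):
        s += (-1.0) ** (k - 1) * math.exp(-2.0 * (k * k - 1.0) * lam * lam)
    return (math.log(2.0) - 2.0 * lam * lam + math.log1p(s)) / math.log(10.0)


def log10_kolmogorov_sf(lam: float) -> float:
    """log10 of the Kolmogorov distribution survival function Q(lam).

    Uses the alternating exponential series for moderate-to-large ``lam``
    and the theta-dual (Jacobi) representation near zero, where the
    alternating series converges slowly.
    """
    if lam <= 0.0:
        return 0.0
    if lam >= 0.75:
        return min(0.0, _log10_kolmogorov_sf_large(lam))
    # CDF via the dual series, accurate for small lam
    t = math.pi * math.pi / (8.0 * lam * lam)
    cdf = (math.sqrt(2.0 * math.pi) / lam) * sum(
        math.exp(-((2 * k - 1) ** 2) * t) for k in range(1, 6)
    )
    sf = 1.0 - cdf
    if sf <= 0.0:
        return -math.inf  # not reachable: sf(0.75) ~ 0.627
    return min(0.0, math.log10(sf))


def signed_ks_test(
    test: Sequence[float], ref: Sequence[float], alpha: float = 0.05
) -> KSResult:
    """Signed two-sample KS test with a log10-domain p-value.

    Parameters
    ----------
    test, ref : array-like
        The two samples (e.g. adhesion areas of a knockdown vs control).
    alpha : float
        Significance level for the -1/0/+1 score.

    Returns
    -------
    KSResult
        ``signed_d`` is ``F_ref - F_test`` evaluated at the point where
        ``|F_ref - F_test|`` is maximal (right-continuous ECDFs), so it
        is positive when ``test`` is stochastically larger.  ``log10_p``
        uses the asymptotic Kolmogorov distribution with effective sample
        size n*m/(n+m).
    """
    test = np.asarray(test, dtype=float).ravel()
    ref = np.asarray(ref, dtype=float).ravel()
    if test.size == 0 or ref.size == 0:
        raise ValueError("both samples must be non-empty")
    n, m = test.size, ref.size
    test_sorted = np.sort(test)
    ref_sorted = np.sort(ref)
    grid = np.concatenate([test_sorted, ref_sorted])
    grid.sort(kind="mergesort")
    f_test = np.searchsorted(test_sorted, grid, side="right") / n
    f_ref = np.searchsorted(ref_sorted, grid, side="right") / m
    diff = f_ref - f_test
    # first point attaining the max |difference|; the tolerance keeps
    # float rounding (k/n arithmetic) from breaking sign ties
    absdiff = np.abs(diff)
    idx = int(np.argmax(absdiff >= absdiff.max() - 1e-12))
    signed_d = float(diff[idx])
    d = abs(signed_d)
    en = n * m / (n + m)
    log10_p = log10_kolmogorov_sf(math.sqrt(en) * d)
    score = int(np.sign(signed_d)) if log10_p < math.log10(alpha) else 0
    return KSResult(signed_d=signed_d, log10_p=log10_p, score=score, n_test=n, n_ref=m)


def _no_change(ks: KSResult, thr: HitThresholds) -> bool:
    return abs(ks.signed_d) < thr.d_nochange or ks.log10_p > thr.log10p_nochange


def classify_gene(
    ks_dmso_vs_control: KSResult,
    ks_noco_vs_dmso: KSResult,
    ks_washout_vs_noco: KSResult,
    thresholds: HitThresholds | None = None,
) -> str:
    """Assign a gene to one of the screen hit categories.

    Categories, evaluated in priority order:

    1. ``increase``  — DMSO-vs-control shifted up past the stringent cut.
    2. ``decrease``  — DMSO-vs-control shifted down past the stringent cut.
    3. ``assembly_blocked`` — no significant change nocodazole-vs-DMSO
       (the adhesions fail to enlarge under microtubule depolymerization).
    4. ``disassembly_blocked`` — normal significant enlargement under
       nocodazole, but no significant change washout-vs-nocodazole (the
       enlarged adhesions fail to disassemble).
    5. ``none``.
    """
    thr = thresholds or HitThresholds()
    for ks in (ks_dmso_vs_control, ks_noco_vs_dmso, ks_washout_vs_noco):
        if ks is None:
            raise ValueError("all three comparisons are required")
    ks0 = ks_dmso_vs_control
    if ks0.signed_d > thr.d_increase and ks0.log10_p < thr.log10p_increase:
        return "increase"
    if ks0.signed_d < thr.d_decrease and ks0.log10_p < thr.log10p_decrease:
        return "decrease"
    if _no_change(ks_noco_vs_dmso, thr):
        return "assembly_blocked"
    noco_increase = (
        ks_noco_vs_dmso.signed_d > 0
        and ks_noco_vs_dmso.log10_p < math.log10(thr.alpha_score)
    )
    if noco_increase and _no_change(ks_washout_vs_noco, thr):
        return "disassembly_blocked"
    return "none"


def summarize_screen(
    calls: Iterable[HitCall], deselect: Sequence[str] = ()
) -> ScreenSummary:
    """Tally hit categories and apply the manual-deselection list.

    Deselected genes (flagged after visual review or on prior-knowledge
    grounds) keep their category but are removed from the hit total.
    """
    calls = list(calls)
    genes = [c.gene for c in calls]
    if len(set(genes)) != len(genes):
        raise ValueError("gene ids must be unique")
    known = set(genes)
    deselected_found = []
    for g in deselect:
        if g in known:
            deselected_found.append(g)
        else:
            warnings.warn(f"deselect gene {g!r} not present in hit calls")
    deselect_set = set(deselected_found)
    counts = {c: 0 for c in CATEGORIES}
    n_deselected_hits = 0
    for call in calls:
        call.deselected = call.gene in deselect_set
        counts[call.category] += 1
        if call.deselected and call.category in ("increase", "decrease"):
            n_deselected_hits += 1
    total = (
        counts["increase"]
        + counts["decrease"]
        - n_deselected_hits
        + counts["assembly_blocked"]
        + counts["disassembly_blocked"]
    )
    return ScreenSummary(
        counts=counts, deselected=deselected_found, total_hits=total
    )


def call_screen(
    areas: Mapping[str, Mapping[str, Sequence[float]]],
    control_gene: str,
    thresholds: HitThresholds | None = None,
    deselect: Sequence[str] = (),
) -> tuple[list[HitCall], ScreenSummary]:
    """Score a whole screen from per-gene, per-condition area samples.

    Parameters
    ----------
    areas : mapping
        ``areas[gene][condition]`` -> adhesion-area sample, with
        conditions ``"DMSO"``, ``"nocodazole"``, ``"washout"``.
    control_gene : str
        Gene whose DMSO sample is the reference for the DMSO-vs-control
        comparison (e.g. the siGFP control).
    """
    thr = thresholds or HitThresholds()
    if control_gene not in areas:
        raise ValueError(f"control gene {control_gene!r} missing from areas")
    control_dmso = areas[control_gene]["DMSO"]
    calls = []
    for gene, cond in areas.items():
        if gene == control_gene:
            continue
        for c in ("DMSO", "nocodazole", "washout"):
            if c not in cond:
                raise ValueError(f"gene {gene!r} missing condition {c!r}")
        ks_ctrl = signed_ks_test(cond["DMSO"], control_dmso, thr.alpha_score)
        ks_noco = signed_ks_test(cond["nocodazole"], cond["DMSO"], thr.alpha_score)
        ks_wash = signed_ks_test(cond["washout"], cond["nocodazole"], thr.alpha_score)
        category = classify_gene(ks_ctrl, ks_noco, ks_wash, thr)
        calls.append(
            HitCall(
                gene=gene,
                ks_dmso_vs_control=ks_ctrl,
                ks_noco_vs_dmso=ks_noco,
                ks_washout_vs_noco=ks_wash,
                category=category,
            )
        )
    summary = summarize_screen(calls, deselect)
    return calls, summary
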