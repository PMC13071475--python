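"""Decision rules that turn codon-model fits into gene-level selection calls.

Two verdicts are produced. A positively selected gene (PSG) requires a
significant branch-site LRT plus at least one credible positively selected
site surviving three false-positive guards: no run of three or more
consecutive candidate codons, no candidate at the first or last codon of
the coding sequence, and candidate status only at empirical-Bayes posterior
>= 0.95. A rapidly evolving gene (REG) requires a significant two-ratio
branch LRT with the foreground dN/dS exceeding the background dN/dS.
Rejections always carry machine-readable reason codes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import LRTResult, lrt

__all__ = [
    "SelectionCall",
    "filter_psg",
    "call_reg",
    "intersect_calls",
    "REASON_P",
    "REASON_RUN",
    "REASON_TERMINAL",
    "REASON_POSTERIOR",
    "REASON_NOT_FASTER",
]

REASON_P = "p_ge_threshold"
REASON_RUN = "consecutive_run"
REASON_TERMINAL = "terminal_site"
REASON_POSTERIOR = "low_posterior"
REASON_NOT_FASTER = "foreground_not_faster"


@dataclass
class SelectionCall:
    """Per-gene outcome of a selection test plus the filter verdict."""

    gene_id: str
    test_type: str  # "branch_site" or "branch"
    lrt: LRTResult
    candidate_sites: list[tuple[int, float]] = field(default_factory=list)
    verdict: str = "rejected"  # "PSG", "REG" or "rejected"
    reject_reasons: list[str] = field(default_factory=list)
    params: dict[str, float] = field(default_factory=dict)

    @property
    def accepted(self) -> bool:
        return self.verdict in ("PSG", "REG")


def _candidate_runs(positions: list[int], min_run: int = 3) -> bool:
    """True if any >=min_run consecutive codon positions are all candidates."""
    run = 1
    for prev, cur in zip(positions, positions[1:]):
        run = run + 1 if cur == prev + 1 else 1
        if run >= min_run:
            return True
    return len(positions) >= min_run and min_run == 1


def filter_psg(
    gene_id: str,
    lrt_result: LRTResult,
    posteriors,
    alignment_length: int | None = None,
    alpha: float = 0.05,
    posterior_threshold: float = 0.95,
    terminal_window: int = 1,
    max_run: int = 3,
) -> SelectionCall:
    """Positively-selected-gene verdict from an LRT and per-site posteriors.

    ``posteriors`` holds one positive-class posterior per codon column
    (1-based positions). The gene is rejected if the LRT p-value is not
    below ``alpha``, if no site reaches ``posterior_threshold``, if
    ``max_run`` or more consecutive sites are all candidates, or if a
    candidate falls within ``terminal_window`` codons of either end of the
    coding sequence; every triggered rule is recorded.
    """
    posteriors = list(posteriors)
    if not posteriors:
        raise ValueError(f"{gene_id}: empty posterior table")
    n = len(posteriors)
    if alignment_length is not None and alignment_length != n:
        raise ValueError(
            f"{gene_id}: posterior table has {n} sites, alignment has "
            f"{alignment_length} codons"
        )
    candidates = [
        (pos, float(p))
        for pos, p in enumerate(posteriors, start=1)
        if p >= posterior_threshold
    ]
    reasons: list[str] = []
    if lrt_result.p >= alpha:
        reasons.append(REASON_P)
    if not candidates:
        reasons.append(REASON_POSTERIOR)
    else:
        positions = [pos for pos, _ in candidates]
        if _candidate_runs(positions, max_run):
            reasons.append(REASON_RUN)
        if any(pos <= terminal_window or pos > n - terminal_window for pos in positions):
            reasons.append(REASON_TERMINAL)
    verdict = "PSG" if not reasons else "rejected"
    return SelectionCall(
        gene_id=gene_id,
        test_type="branch_site",
        lrt=lrt_result,
        candidate_sites=candidates,
        verdict=verdict,
        reject_reasons=reasons,
    )


def call_reg(gene_id: str, fit_m0, fit_m2, alpha: float = 0.05) -> SelectionCall:
    """Rapidly-evolving-gene verdict from one-ratio vs two-ratio branch fits.

    REG iff the df=1 LRT is significant at ``alpha`` and the fitted
    foreground dN/dS exceeds the background dN/dS.
    """
    test = lrt(fit_m0.lnL, fit_m2.lnL, df=1)
    w_bg = fit_m2.params["omega_background"]
    w_fg = fit_m2.params["omega_foreground"]
    reasons: list[str] = []
    if test.p >= alpha:
        reasons.append(REASON_P)
    if w_fg <= w_bg:
        reasons.append(REASON_NOT_FASTER)
    return SelectionCall(
        gene_id=gene_id,
        test_type="branch",
        lrt=test,
        verdict="REG" if not reasons else "rejected",
        reject_reasons=reasons,
        params={"omega_background": w_bg, "omega_foreground": w_fg},
    )


def intersect_calls(psgs, regs) -> list[str]:
    """Genes accepted by both screens, as a sorted id list.

    Accepts lists of :class:`SelectionCall` (only accepted calls count) or
    plain gene-id iterables.
    """

    def ids(calls):
        out = set()
        for c in calls:
            if isinstance(c, SelectionCall):
                if c.accepted:
                    out.add(c.gene_id)
            else:
                out.add(str(c))
        return out

    return sorted(ids(psgs) & ids(regs))
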