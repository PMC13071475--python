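"""Goldman–Yang codon substitution models: likelihood, fitting and LRTs.

The substitution process runs over the 61 sense codons. Instantaneous rates
between codons differing at one nucleotide are

    q_ij ∝ pi_j * kappa^[transition] * omega^[nonsynonymous]

with all multi-nucleotide changes forbidden, and the generator scaled so the
expected substitution rate at stationarity is one (branch lengths are then
expected substitutions per codon site). Four model configurations are
supported, mirroring the codeml settings they correspond to:

=================  =====================================================
``M0``             one dN/dS ratio omega shared by every branch
``branch``         two ratios: omega_background and omega_foreground
                   (codeml model=2, NSsites=0)
``branch-site``    Model A: site classes 0 (0<omega0<1), 1 (omega=1) and
                   2a/2b where foreground branches take omega2>=1
``branch-site-null``  Model A with omega2 fixed at 1 (the LRT null)
=================  =====================================================

Fitting follows the statsmodels convention: build a :class:`CodonModel`
from data, call :meth:`~CodonModel.fit`, and get a
:class:`CodonModelResults` carrying estimates, the log-likelihood and a
``summary()`` table. Likelihood-ratio tests compare two results (or two raw
log-likelihoods) against a chi-square upper tail.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.optimize import minimize
from scipy.stats import chi2

from . import genetics
from .seqio import CodonAlignment, SpeciesTree

__all__ = [
    "build_rate_matrix",
    "estimate_f3x4",
    "uniform_codon_freqs",
    "transition_matrix",
    "CodonModel",
    "CodonModelResults",
    "LRTResult",
    "lrt",
]

N = genetics.N_CODONS

# --- static structure of the single-nucleotide-change graph ----------------
# _PAIR_I/_PAIR_J: ordered codon index pairs one nucleotide apart;
# _PAIR_TS / _PAIR_NONSYN: whether that change is a transition / changes the
# encoded amino acid.
_pi_list, _pj_list, _ts_list, _ns_list = [], [], [], []
for _i, _ci in enumerate(genetics.CODONS):
    for _j, _cj in enumerate(genetics.CODONS):
        if _i == _j:
            continue
        diffs = [(a, b) for a, b in zip(_ci, _cj) if a != b]
        if len(diffs) != 1:
            continue
        _pi_list.append(_i)
        _pj_list.append(_j)
        _ts_list.append(genetics.is_transition(*diffs[0]))
        _ns_list.append(genetics.CODON_AA[_i] != genetics.CODON_AA[_j])
_PAIR_I = np.array(_pi_list)
_PAIR_J = np.array(_pj_list)
_PAIR_TS = np.array(_ts_list)
_PAIR_NONSYN = np.array(_ns_list)

KAPPA_BOUNDS = (1e-3, 100.0)
OMEGA_BOUNDS = (1e-6, 50.0)
_PROP_EPS = 1e-6


def uniform_codon_freqs() -> np.ndarray:
    """Uniform distribution over the 61 sense codons."""
    return np.full(N, 1.0 / N)


def build_rate_matrix(
    kappa: float, omega: float, pi: np.ndarray, scale: float | None = None
) -> np.ndarray:
    """GY94 rate generator, scaled to one expected substitution per unit time.

    Rows sum to zero; q_ij = 0 for multi-nucleotide changes; detailed balance
    pi_i q_ij = pi_j q_ji holds because the unscaled exchangeability is
    symmetric in (i, j).

    By default the generator is divided by its own stationary mean rate so
    branch lengths read as expected substitutions per codon under this
    process. Passing ``scale`` divides by that factor instead — used by the
    site-class mixture models, where all classes must share one time scale
    (a site class with omega > 1 then genuinely evolves faster, it does not
    merely shift its substitution spectrum).
    """
    if kappa <= 0:
        raise ValueError(f"kappa must be positive, got {kappa}")
    if omega < 0:
        raise ValueError(f"omega must be non-negative, got {omega}")
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (N,):
        raise ValueError(f"pi must have {N} entries")
    if np.any(pi <= 0):
        raise ValueError("degenerate codon frequencies: zero-mass codon(s)")
    if abs(pi.sum() - 1.0) > 1e-8:
        raise ValueError("codon frequencies must sum to 1")
    Q = np.zeros((N, N))
    rates = pi[_PAIR_J] * np.where(_PAIR_TS, kappa, 1.0) * np.where(
        _PAIR_NONSYN, omega, 1.0
    )
    Q[_PAIR_I, _PAIR_J] = rates
    np.fill_diagonal(Q, -Q.sum(axis=1))
    if scale is None:
        scale = -np.dot(pi, np.diag(Q))
    if scale <= 0:
        raise ValueError("rate matrix has zero mean rate")
    return Q / scale


def stationary_mean_rate(kappa: float, omega: float, pi: np.ndarray) -> float:
    """Mean rate of the unscaled GY94 generator at stationarity."""
    rates = pi[_PAIR_J] * np.where(_PAIR_TS, kappa, 1.0) * np.where(
        _PAIR_NONSYN, omega, 1.0
    )
    return float(np.bincount(_PAIR_I, weights=rates, minlength=N) @ pi)


def estimate_f3x4(aln: CodonAlignment, floor: float = 1e-8) -> np.ndarray:
    """F3x4 codon frequencies from position-specific nucleotide counts.

    pi(c1 c2 c3) ∝ f1(c1) f2(c2) f3(c3), renormalised over the 61 sense
    codons. A small floor keeps every sense codon at positive mass so the
    rate generator stays irreducible on low-diversity alignments.
    """
    counts = np.zeros((3, 4))
    nuc_idx = {n: k for k, n in enumerate(genetics.NUCLEOTIDES)}
    n_codons_seen = 0
    for seq in aln.sequences.values():
        for i in range(0, len(seq), 3):
            codon = seq[i : i + 3]
            if any(ch not in nuc_idx for ch in codon):
                continue
            n_codons_seen += 1
            for pos, ch in enumerate(codon):
                counts[pos, nuc_idx[ch]] += 1
    if n_codons_seen == 0:
        raise ValueError("alignment has no fully resolved codons")
    freqs = counts / counts.sum(axis=1, keepdims=True)
    pi = np.array(
        [
            freqs[0, nuc_idx[c[0]]] * freqs[1, nuc_idx[c[1]]] * freqs[2, nuc_idx[c[2]]]
            for c in genetics.CODONS
        ]
    )
    pi = np.maximum(pi, floor)
    return pi / pi.sum()


def transition_matrix(Q: np.ndarray, pi: np.ndarray, t: float) -> np.ndarray:
    """P(t) = exp(Qt) via the symmetric eigendecomposition of a reversible Q."""
    lam, U, sq, inv_sq = _reversible_eig(Q, pi)
    return _p_from_eig(lam, U, sq, inv_sq, t)


def _reversible_eig(Q: np.ndarray, pi: np.ndarray):
    sq = np.sqrt(pi)
    inv_sq = 1.0 / sq
    B = (Q * sq[:, None]) * inv_sq[None, :]
    B = 0.5 * (B + B.T)  # symmetrise against round-off
    lam, U = eigh(B)
    return lam, U, sq, inv_sq


def _p_from_eig(lam, U, sq, inv_sq, t: float) -> np.ndarray:
    P = (inv_sq[:, None] * U) @ (np.exp(lam * t)[:, None] * (U.T * sq[None, :]))
    np.clip(P, 0.0, None, out=P)
    P /= P.sum(axis=1, keepdims=True)
    return P


# ---------------------------------------------------------------------------
# Tree indexing and alignment encoding
# ---------------------------------------------------------------------------

@dataclass
class _TreeIndex:
    """Flat postorder arrays for pruning: children, branch lengths, flags."""

    postorder: list[int]            # node ids, root last
    children: list[list[int]]       # per node id
    length: np.ndarray              # branch length above each node (root: 0)
    foreground: np.ndarray          # branch above node is foreground
    leaf_taxon: dict[int, str]      # node id -> taxon for leaves
    root: int

    @classmethod
    def from_species_tree(cls, st: SpeciesTree) -> "_TreeIndex":
        nodes = list(st.tree.postorder_node_iter())
        ids = {node: i for i, node in enumerate(nodes)}
        children = [[] for _ in nodes]
        length = np.zeros(len(nodes))
        fg = np.zeros(len(nodes), dtype=bool)
        leaf_taxon: dict[int, str] = {}
        root = ids[st.tree.seed_node]
        for node, i in ids.items():
            for ch in node.child_nodes():
                children[i].append(ids[ch])
            if node is not st.tree.seed_node:
                bl = node.edge.length
                if bl is None:
                    bl = 0.0
                if bl < 0:
                    raise ValueError(
                        f"negative branch length above node {i}"
                    )
                length[i] = bl
                fg[i] = getattr(node, "is_foreground", False)
            if node.is_leaf():
                leaf_taxon[i] = node.taxon.label
        return cls([ids[n] for n in nodes], children, length, fg, leaf_taxon, root)

    @property
    def n_nodes(self) -> int:
        return len(self.children)


def encode_alignment(aln: CodonAlignment, taxa_order: list[str]) -> np.ndarray:
    """Map codons to state indices; -1 for gap/ambiguous/stop (missing data)."""
    mat = np.empty((len(taxa_order), aln.n_codons), dtype=np.int16)
    for r, taxon in enumerate(taxa_order):
        seq = aln.sequences[taxon]
        for s in range(aln.n_codons):
            mat[r, s] = genetics.CODON_INDEX.get(seq[3 * s : 3 * s + 3], -1)
    return mat


# ---------------------------------------------------------------------------
# Results containers
# ---------------------------------------------------------------------------

@dataclass
class LRTResult:
    """Likelihood-ratio test of nested codon models.

    stat = 2(lnL_alt - lnL_null), clamped at zero; p is the chi-square
    upper-tail probability at ``df`` degrees of freedom.
    """

    stat: float
    df: int
    p: float

    @property
    def significant(self) -> bool:
        return self.p < 0.05


def lrt(lnL_null: float, lnL_alt: float, df: int = 1) -> LRTResult:
    if not (np.isfinite(lnL_null) and np.isfinite(lnL_alt)):
        raise ValueError("non-finite log-likelihood in LRT")
    if df < 1:
        raise ValueError("df must be >= 1")
    stat = max(0.0, 2.0 * (lnL_alt - lnL_null))
    return LRTResult(stat=stat, df=df, p=float(chi2.sf(stat, df)))


_MODEL_ALIASES = {
    "m0": "M0",
    "one-ratio": "M0",
    "m2": "branch",
    "two-ratio": "branch",
    "branch": "branch",
    "ma": "branch-site",
    "branch-site": "branch-site",
    "ma0": "branch-site-null",
    "branch-site-null": "branch-site-null",
}

_N_FREE = {"M0": 2, "branch": 3, "branch-site": 5, "branch-site-null": 4}


@dataclass
class CodonModelResults:
    """Fitted codon model: estimates, log-likelihood and diagnostics."""

    model: "CodonModel"
    model_name: str
    lnL: float
    params: dict[str, float]
    converged: bool
    n_iter: int
    n_free_params: int

    def lrt(self, null: "CodonModelResults", df: int | None = None) -> LRTResult:
        """LRT of this (alternative) fit against a nested null fit."""
        if df is None:
            df = self.n_free_params - null.n_free_params
        return lrt(null.lnL, self.lnL, df)

    def site_posteriors(self) -> pd.DataFrame:
        """Per-codon-site posterior of the positive-selection class (NEB).

        Naive empirical Bayes at the MLEs: the posterior of classes 2a+2b
        under Model A, evaluated with the fitted parameter values. Only
        defined for branch-site fits. Columns: ``site`` (1-based),
        ``posterior``, ``flavor``.
        """
        if self.model_name not in ("branch-site", "branch-site-null"):
            raise ValueError(
                f"site posteriors require a branch-site fit, got {self.model_name}"
            )
        post = self.model._site_class_posteriors(self.params)
        return pd.DataFrame(
            {
                "site": np.arange(1, len(post) + 1),
                "posterior": post,
                "flavor": "NEB",
            }
        )

    def summary(self) -> str:
        lines = [
            "Codon substitution model fit",
            "=" * 46,
            f"model:          {self.model_name}",
            f"taxa:           {len(self.model.alignment.taxa)}",
            f"codon sites:    {self.model.alignment.n_codons}",
            f"log-likelihood: {self.lnL:.6f}",
            f"free params:    {self.n_free_params}",
            f"converged:      {self.converged}  (n_iter={self.n_iter})",
            "-" * 46,
        ]
        for k, v in self.params.items():
            lines.append(f"{k:<18} {v:.5f}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<CodonModelResults {self.model_name} lnL={self.lnL:.4f} "
            f"converged={self.converged}>"
        )


# ---------------------------------------------------------------------------
# The model
# ---------------------------------------------------------------------------

class CodonModel:
    """Codon substitution model bound to an alignment and a species tree.

    Parameters
    ----------
    alignment:
        In-frame codon alignment; gaps, Ns and stop codons are treated as
        missing data (partial likelihood one over all 61 states).
    tree:
        Rooted species tree with branch lengths in expected substitutions
        per codon site; foreground branches must be tagged for the branch
        and branch-site models. Branch lengths are held fixed at their
        input values during fitting.
    freq:
        Equilibrium codon frequency model: ``"F3x4"`` (default, estimated
        from the alignment), ``"F61"`` (observed codon frequencies) or
        ``"uniform"``.
    """

    def __init__(self, alignment: CodonAlignment, tree: SpeciesTree, freq: str = "F3x4"):
        missing = set(tree.taxa) ^ set(alignment.taxa)
        if missing:
            raise ValueError(f"alignment/tree taxon mismatch: {sorted(missing)}")
        self.alignment = alignment
        self.tree = tree
        self.index = _TreeIndex.from_species_tree(tree)
        codes = encode_alignment(alignment, [self.index.leaf_taxon[i]
                                             for i in sorted(self.index.leaf_taxon)])
        self._leaf_rows = {i: r for r, i in enumerate(sorted(self.index.leaf_taxon))}
        # site-pattern compression
        patterns, inverse, weights = np.unique(
            codes.T, axis=0, return_inverse=True, return_counts=True
        )
        self._patterns = patterns.T  # (ntaxa, npat)
        self._pattern_of_site = inverse.ravel()
        self._weights = weights.astype(float)
        if freq == "F3x4":
            self.pi = estimate_f3x4(alignment)
        elif freq == "F61":
            self.pi = self._f61()
        elif freq == "uniform":
            self.pi = uniform_codon_freqs()
        else:
            raise ValueError(f"unknown frequency model {freq!r}")
        self.freq = freq

    # -- frequency helpers --------------------------------------------------
    def _f61(self, floor: float = 1e-8) -> np.ndarray:
        counts = np.zeros(N)
        for seq in self.alignment.sequences.values():
            for i in range(0, len(seq), 3):
                idx = genetics.CODON_INDEX.get(seq[i : i + 3])
                if idx is not None:
                    counts[idx] += 1
        if counts.sum() == 0:
            raise ValueError("alignment has no fully resolved codons")
        pi = np.maximum(counts / counts.sum(), floor)
        return pi / pi.sum()

    # -- pruning ------------------------------------------------------------
    def _pattern_logliks(self, P_by_node: dict[int, np.ndarray]) -> np.ndarray:
        """Felsenstein pruning over site patterns with per-node rescaling.

        ``P_by_node[child]`` may be one (61, 61) matrix or a stack of C
        matrices, one per site class; classes are pruned in a single
        batched pass. Returns log-likelihood per pattern, shape (npat,) or
        (C, npat).
        """
        idx = self.index
        npat = self._patterns.shape[1]
        some = next(iter(P_by_node.values()))
        batched = some.ndim == 3
        C = some.shape[0] if batched else 1
        partial: dict[int, np.ndarray] = {}
        logscale = np.zeros((C, npat))
        eye = np.eye(N)
        for node in idx.postorder:
            kids = idx.children[node]
            if not kids:
                states = self._patterns[self._leaf_rows[node]]
                L = np.ones((npat, N))
                obs = states >= 0
                L[obs] = eye[states[obs]]
                partial[node] = np.broadcast_to(L, (C, npat, N))
                continue
            L = np.ones((C, npat, N))
            for ch in kids:
                P = P_by_node[ch]
                if P.ndim == 2:
                    P = np.broadcast_to(P, (C, N, N))
                L = L * (partial.pop(ch) @ P.transpose(0, 2, 1))
            m = L.max(axis=2)
            if np.any(m <= 0):
                raise FloatingPointError(
                    f"zero partial likelihood at pattern(s) "
                    f"{np.nonzero((m <= 0).any(axis=0))[0][:5]}"
                )
            L /= m[:, :, None]
            logscale += np.log(m)
            partial[node] = L
        root_L = partial[idx.root] @ self.pi
        out = np.log(root_L) + logscale
        return out if batched else out[0]

    def _edge_Ps(self, omega_by_branch_class: dict[bool, float], kappa: float):
        """Transition matrices per node, with one Q per branch class."""
        classes = self._edge_Ps_multi([omega_by_branch_class], kappa)
        return {node: P[0] for node, P in classes.items()}

    def _edge_Ps_multi(
        self,
        class_omegas: list[dict[bool, float]],
        kappa: float,
        qfactor: float | None = None,
    ):
        """Per-node stacks of transition matrices, one layer per site class.

        ``qfactor`` imposes one common time scale on every class (mixture
        models); when None each omega's generator is normalised on its own
        (single-class models). Eigendecompositions are shared across classes
        and branch classes that use the same omega.
        """
        idx = self.index
        eig_by_omega = {}
        for comb in class_omegas:
            for w in comb.values():
                if w not in eig_by_omega:
                    Q = build_rate_matrix(kappa, w, self.pi, scale=qfactor)
                    eig_by_omega[w] = _reversible_eig(Q, self.pi)
        P_cache: dict[tuple[float, float], np.ndarray] = {}
        out: dict[int, np.ndarray] = {}
        for node in idx.postorder:
            if node == idx.root:
                continue
            t = idx.length[node]
            fg = bool(idx.foreground[node])
            layers = []
            for comb in class_omegas:
                w = comb[fg]
                key = (w, t)
                if key not in P_cache:
                    P_cache[key] = _p_from_eig(*eig_by_omega[w], t)
                layers.append(P_cache[key])
            out[node] = np.stack(layers)
        return out

    # -- per-model likelihoods ----------------------------------------------
    def loglik(self, model_name: str, params: dict[str, float]) -> float:
        """Log-likelihood of the data at the given parameter values."""
        name = _MODEL_ALIASES[model_name.lower()]
        if name == "M0":
            site = self._pattern_logliks(
                self._edge_Ps({False: params["omega"], True: params["omega"]},
                              params["kappa"])
            )
        elif name == "branch":
            self._require_foreground()
            site = self._pattern_logliks(
                self._edge_Ps(
                    {False: params["omega_background"],
                     True: params["omega_foreground"]},
                    params["kappa"],
                )
            )
        else:
            site = self._branch_site_pattern_logliks(params)
        return float(np.dot(self._weights, site))

    def _require_foreground(self) -> None:
        if not self.tree.foreground_taxa:
            raise ValueError(
                "branch/branch-site models need a foreground-tagged tree"
            )

    def _branch_site_class_table(self, params):
        """Model A classes as (proportion, background omega, foreground omega)."""
        p0, p1 = params["p0"], params["p1"]
        w0, w2 = params["omega0"], params["omega2"]
        tot = p0 + p1
        p2 = 1.0 - tot
        return [
            (p0, w0, w0),
            (p1, 1.0, 1.0),
            (p2 * p0 / tot, w0, w2),
            (p2 * p1 / tot, 1.0, w2),
        ]

    def _branch_site_class_logs(self, params) -> np.ndarray:
        """log(class proportion) + per-pattern class log-likelihood, (4, npat)."""
        self._require_foreground()
        classes = self._branch_site_class_table(params)
        # one time scale for all classes, set so the class-weighted mean
        # rate on background branches is 1: branch lengths keep their
        # substitutions-per-codon reading while omega2 > 1 accelerates
        # foreground evolution in the selected classes
        qfactor = sum(
            prop * stationary_mean_rate(params["kappa"], w_bg, self.pi)
            for prop, w_bg, _ in classes
        )
        Ps = self._edge_Ps_multi(
            [{False: wb, True: wf} for _, wb, wf in classes],
            params["kappa"],
            qfactor=qfactor,
        )
        site = self._pattern_logliks(Ps)
        props = np.array([max(p, 1e-300) for p, _, _ in classes])
        return np.log(props)[:, None] + site

    def _branch_site_pattern_logliks(self, params) -> np.ndarray:
        return _logsumexp_rows(self._branch_site_class_logs(params))

    def _site_class_posteriors(self, params) -> np.ndarray:
        """NEB posterior of the positively selected classes (2a+2b), per site."""
        logs = self._branch_site_class_logs(params)
        post_pat = np.exp(_logsumexp_rows(logs[2:]) - _logsumexp_rows(logs))
        return post_pat[self._pattern_of_site]

    # -- fitting ------------------------------------------------------------
    def fit(
        self,
        model: str = "M0",
        starts: int = 3,
        seed: int = 0,
        tol: float = 1e-8,
        maxiter: int = 500,
    ) -> CodonModelResults:
        """Maximise the log-likelihood by bounded quasi-Newton search.

        ``starts`` seeded random restarts guard against local optima; the
        best optimum is kept and ``converged`` reports the optimizer status
        honestly. Branch lengths stay fixed at the input tree's values.
        """
        name = _MODEL_ALIASES[model.lower()]
        if name != "M0":
            self._require_foreground()
        rng = np.random.default_rng(seed)
        pack, unpack, bounds, default = _PARAMETERISATIONS[name]

        def objective(x):
            try:
                return -self.loglik(name, unpack(x))
            except FloatingPointError:
                return 1e12

        best = None
        n_iter_total = 0
        for s in range(max(1, starts)):
            x0 = default() if s == 0 else _random_start(bounds, rng)
            res = minimize(
                objective,
                x0,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": maxiter, "ftol": tol, "gtol": 1e-8},
            )
            n_iter_total += res.nit
            if best is None or res.fun < best.fun:
                best = res
        params = unpack(best.x)
        if name == "branch-site-null":
            params["omega2"] = 1.0
        return CodonModelResults(
            model=self,
            model_name=name,
            lnL=-float(best.fun),
            params=params,
            converged=bool(best.success),
            n_iter=n_iter_total,
            n_free_params=_N_FREE[name],
        )


def _logsumexp_rows(a: np.ndarray) -> np.ndarray:
    m = a.max(axis=0)
    return m + np.log(np.exp(a - m[None, :]).sum(axis=0))


def _random_start(bounds, rng) -> np.ndarray:
    return np.array([rng.uniform(lo, hi) for lo, hi in bounds])


# optimisation is carried out on log(kappa) and log(omega) so the box
# bounds stay well scaled; mixture proportions use (t, r) with
# p0 = t*r, p1 = t*(1-r)
_LOG_K = (np.log(KAPPA_BOUNDS[0]), np.log(KAPPA_BOUNDS[1]))
_LOG_W = (np.log(OMEGA_BOUNDS[0]), np.log(OMEGA_BOUNDS[1]))
_LOG_W01 = (np.log(OMEGA_BOUNDS[0]), 0.0)
_LOG_W2 = (0.0, np.log(OMEGA_BOUNDS[1]))
_UNIT = (_PROP_EPS, 1.0 - _PROP_EPS)


def _unpack_m0(x):
    return {"kappa": float(np.exp(x[0])), "omega": float(np.exp(x[1]))}


def _unpack_branch(x):
    return {
        "kappa": float(np.exp(x[0])),
        "omega_background": float(np.exp(x[1])),
        "omega_foreground": float(np.exp(x[2])),
    }


def _unpack_bs(x):
    t, r = x[1], x[2]
    return {
        "kappa": float(np.exp(x[0])),
        "p0": float(t * r),
        "p1": float(t * (1.0 - r)),
        "omega0": float(np.exp(x[3])),
        "omega2": float(np.exp(x[4])) if len(x) > 4 else 1.0,
    }


_PARAMETERISATIONS = {
    "M0": (
        None,
        _unpack_m0,
        [_LOG_K, _LOG_W],
        lambda: np.array([np.log(2.0), np.log(0.3)]),
    ),
    "branch": (
        None,
        _unpack_branch,
        [_LOG_K, _LOG_W, _LOG_W],
        lambda: np.array([np.log(2.0), np.log(0.3), np.log(0.5)]),
    ),
    "branch-site": (
        None,
        _unpack_bs,
        [_LOG_K, _UNIT, _UNIT, _LOG_W01, _LOG_W2],
        lambda: np.array([np.log(2.0), 0.85, 0.7, np.log(0.2), np.log(2.0)]),
    ),
    "branch-site-null": (
        None,
        _unpack_bs,
        [_LOG_K, _UNIT, _UNIT, _LOG_W01],
        lambda: np.array([np.log(2.0), 0.85, 0.7, np.log(0.2)]),
    ),
}
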