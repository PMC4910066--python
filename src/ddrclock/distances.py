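"""Pairwise nucleotide identity and evolutionary distance estimators.

Five models are provided: uncorrected ``p``, Jukes–Cantor (``jc69``),
Kimura two-parameter (``k2p``), Tamura–Nei (``tn93``), and
``mcl_composite`` — a Tamura–Nei-form distance whose rate parameters are
estimated once by maximizing the composite (pairwise-summed) likelihood
over an entire alignment set, emulating the documented default behaviour
of MEGA's "maximum composite likelihood" method. The emulation is not a
bit-exact clone of MEGA; its likelihood is stated exactly in the methods
documentation.

Gap handling is pairwise deletion throughout: an alignment column
contributes to a pair only when both members carry an unambiguous base.
Distances that hit saturation (a logarithm argument <= 0, or a composite
likelihood maximized at the branch-length bound) are returned as
``math.inf`` and flagged, never as silent NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import minimize

from ddrclock.repeatio import AlignmentSet, SeqRecordNT

MODEL_NAMES = ("p", "jc69", "k2p", "tn93", "mcl_composite")

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
# purine transition A<->G; pyrimidine transition C<->T
_TRANSITION_PAIRS = {frozenset("AG"), frozenset("CT")}


class ComparisonError(ValueError):
    """No comparable sites between two sequences, or malformed input."""


class SaturationError(ValueError):
    """Raised only when a caller explicitly demands a finite distance."""


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero, matching how printed tables round."""
    factor = 10.0**ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class DistanceModel:
    """A named pairwise distance model.

    ``gamma_shape`` is accepted for forward compatibility but must stay
    ``None`` (uniform rates); pairwise deletion is always on.
    """

    name: str = "mcl_composite"
    gamma_shape: float | None = None

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ValueError(
                f"unknown model {self.name!r}; choose from {MODEL_NAMES}"
            )
        if self.gamma_shape is not None:
            raise NotImplementedError("gamma rate variation is not supported")


def as_model(model: "DistanceModel | str") -> DistanceModel:
    return DistanceModel(model) if isinstance(model, str) else model


@dataclass(frozen=True)
class PairwiseComparison:
    """Site-pattern summary of two aligned sequences under pairwise deletion."""

    identical: int
    compared: int
    transitions: int
    transversions: int
    base_freqs: tuple[float, float, float, float]

    @property
    def p_distance(self) -> float:
        return 1.0 - self.identical / self.compared

    @property
    def identity_pct(self) -> float:
        """Percent identity, rounded half-up to one decimal."""
        return round_half_up(100.0 * self.identical / self.compared, 1)


def _as_seq(x: "str | SeqRecordNT") -> str:
    return x.seq if isinstance(x, SeqRecordNT) else x


def compare_pair(a: "str | SeqRecordNT", b: "str | SeqRecordNT") -> PairwiseComparison:
    """Count identical/compared sites, transitions and transversions.

    Columns where either sequence has a gap or an ambiguity (N/X) are
    excluded from ``compared``. Base frequencies are pooled over both
    sequences' compared positions.
    """
    sa, sb = _as_seq(a), _as_seq(b)
    if len(sa) != len(sb):
        raise ComparisonError(
            f"aligned lengths differ ({len(sa)} vs {len(sb)})"
        )
    identical = compared = transitions = transversions = 0
    counts = np.zeros(4)
    for x, y in zip(sa, sb):
        if x not in _BASE_INDEX or y not in _BASE_INDEX:
            continue
        compared += 1
        counts[_BASE_INDEX[x]] += 1
        counts[_BASE_INDEX[y]] += 1
        if x == y:
            identical += 1
        elif frozenset((x, y)) in _TRANSITION_PAIRS:
            transitions += 1
        else:
            transversions += 1
    if compared == 0:
        raise ComparisonError("no comparable (ungapped, unambiguous) sites")
    freqs = counts / counts.sum()
    return PairwiseComparison(
        identical=identical,
        compared=compared,
        transitions=transitions,
        transversions=transversions,
        base_freqs=tuple(freqs),
    )


def _pair_counts(sa: str, sb: str) -> np.ndarray:
    """4x4 matrix of (base in a, base in b) counts over compared sites."""
    F = np.zeros((4, 4))
    for x, y in zip(sa, sb):
        i = _BASE_INDEX.get(x)
        j = _BASE_INDEX.get(y)
        if i is not None and j is not None:
            F[i, j] += 1
    return F


# ---------------------------------------------------------------------------
# closed-form distances


def _jc69(p: float) -> float:
    arg = 1.0 - 4.0 * p / 3.0
    return math.inf if arg <= 0 else -0.75 * math.log(arg)


def _k2p(P: float, Q: float) -> float:
    a1 = 1.0 - 2.0 * P - Q
    a2 = 1.0 - 2.0 * Q
    if a1 <= 0 or a2 <= 0:
        return math.inf
    return -0.5 * math.log(a1) - 0.25 * math.log(a2)


def _tn93(cmp_: PairwiseComparison, sa: str, sb: str) -> float:
    gA, gC, gG, gT = cmp_.base_freqs
    gR, gY = gA + gG, gC + gT
    n = cmp_.compared
    # split transitions into purine (A<->G) and pyrimidine (C<->T)
    p1 = p2 = 0
    for x, y in zip(sa, sb):
        if frozenset((x, y)) == frozenset("AG"):
            p1 += 1
        elif frozenset((x, y)) == frozenset("CT"):
            p2 += 1
    P1, P2 = p1 / n, p2 / n
    Q = cmp_.transversions / n
    if min(gA, gC, gG, gT) <= 0:
        # degenerate composition: fall back is the caller's choice
        raise ComparisonError(
            "tn93 undefined: a base is absent from the compared sites"
        )
    k1 = 2.0 * gA * gG / gR
    k2 = 2.0 * gT * gC / gY
    k3 = 2.0 * (gR * gY - gA * gG * gY / gR - gT * gC * gR / gY)
    w1 = 1.0 - P1 / k1 - Q / (2.0 * gR)
    w2 = 1.0 - P2 / k2 - Q / (2.0 * gY)
    w3 = 1.0 - Q / (2.0 * gR * gY)
    if w1 <= 0 or w2 <= 0 or w3 <= 0:
        return math.inf
    return -k1 * math.log(w1) - k2 * math.log(w2) - k3 * math.log(w3)


# ---------------------------------------------------------------------------
# Tamura–Nei rate matrix machinery (shared by mcl_composite and the simulator)


def tn93_rate_matrix(
    pi: Sequence[float], kappa1: float, kappa2: float
) -> np.ndarray:
    """Tamura–Nei generator over ACGT, scaled to one expected
    substitution per site per unit time.

    ``kappa1``/``kappa2`` are the purine- and pyrimidine-transition rate
    multipliers relative to transversions.
    """
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (4,) or not math.isclose(pi.sum(), 1.0, abs_tol=1e-8):
        raise ValueError("pi must be a 4-vector summing to 1")
    Q = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            pair = frozenset((_BASES[i], _BASES[j]))
            if pair == frozenset("AG"):
                Q[i, j] = kappa1 * pi[j]
            elif pair == frozenset("CT"):
                Q[i, j] = kappa2 * pi[j]
            else:
                Q[i, j] = pi[j]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    rate = -np.dot(pi, np.diag(Q))
    return Q / rate


def _eigen_reversible(Q: np.ndarray, pi: np.ndarray):
    """Eigendecompose a reversible generator via the symmetrizing similarity."""
    d = np.sqrt(pi)
    S = (Q * d[:, None]) / d[None, :]
    lam, U = np.linalg.eigh((S + S.T) / 2.0)
    # P(t) = D^{-1/2} U diag(e^{lam t}) U' D^{1/2}
    A = U / d[:, None]
    B = U.T * d[None, :]
    return lam, A, B


def _transition_probs(lam, A, B, t: np.ndarray) -> np.ndarray:
    """Batched P(t): shape (len(t), 4, 4)."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    E = np.exp(np.outer(t, lam))  # (m, 4)
    P = np.einsum("ik,mk,kj->mij", A, E, B)
    return np.clip(P, 1e-300, None)


@dataclass(frozen=True)
class MclParams:
    """Shared Tamura–Nei parameters fitted by composite likelihood."""

    pi: tuple[float, float, float, float]
    kappa1: float
    kappa2: float
    log_composite_likelihood: float


_D_MAX = 10.0  # branch lengths at this bound are reported saturated


def _profile_distances(lam, A, B, pi, Fs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized golden-section maximization of each pair's log-likelihood
    over its own branch length. Returns (d_hat, loglik) arrays."""
    log_pi = np.log(pi)

    def negll(d: np.ndarray) -> np.ndarray:
        P = _transition_probs(lam, A, B, d)
        return -np.einsum("mij,mij->m", Fs, np.log(P) + log_pi[None, :, None])

    gr = (math.sqrt(5.0) - 1.0) / 2.0
    a = np.full(Fs.shape[0], 1e-9)
    b = np.full(Fs.shape[0], _D_MAX)
    c = b - gr * (b - a)
    d_ = a + gr * (b - a)
    fc, fd = negll(c), negll(d_)
    for _ in range(70):
        left = fc < fd
        b = np.where(left, d_, b)
        a = np.where(left, a, c)
        c = b - gr * (b - a)
        d_ = a + gr * (b - a)
        fc, fd = negll(c), negll(d_)
    d_hat = (a + b) / 2.0
    return d_hat, -negll(d_hat)


def fit_mcl(seqs: Sequence[str], pairs: "Sequence[tuple[int, int]] | None" = None) -> MclParams:
    """Fit shared TN93 rate ratios by maximum composite likelihood.

    The composite likelihood is the sum over all (or the given) sequence
    pairs of each pair's multinomial log-likelihood under a common rate
    matrix, with every pair's branch length profiled out at its own
    maximum. Base frequencies are fixed at the pooled empirical values.
    """
    n = len(seqs)
    if n < 2:
        raise ComparisonError("mcl_composite requires at least 2 sequences")
    if pairs is None:
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    Fs = np.stack([_pair_counts(seqs[i], seqs[j]) for i, j in pairs])
    Fs = (Fs + Fs.transpose(0, 2, 1)) / 2.0  # reversible: direction is arbitrary
    if np.any(Fs.sum(axis=(1, 2)) == 0):
        bad = [pairs[k] for k in np.where(Fs.sum(axis=(1, 2)) == 0)[0]]
        raise ComparisonError(f"no comparable sites for pair(s) {bad}")
    pooled = Fs.sum(axis=0)
    pi = (pooled.sum(axis=0) + pooled.sum(axis=1)) / (2.0 * pooled.sum())
    pi = np.clip(pi, 1e-6, None)
    pi = pi / pi.sum()

    def objective(log_kappas: np.ndarray) -> float:
        k1, k2 = np.exp(np.clip(log_kappas, -6, 6))
        Q = tn93_rate_matrix(pi, k1, k2)
        lam, A, B = _eigen_reversible(Q, pi)
        _, ll = _profile_distances(lam, A, B, pi, Fs)
        return -float(ll.sum())

    res = minimize(
        objective,
        x0=np.log([2.0, 2.0]),
        method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 200},
    )
    k1, k2 = np.exp(np.clip(res.x, -6, 6))
    return MclParams(
        pi=tuple(pi),
        kappa1=float(k1),
        kappa2=float(k2),
        log_composite_likelihood=-float(res.fun),
    )


def mcl_distances(
    seqs: Sequence[str],
    pairs: Sequence[tuple[int, int]],
    params: MclParams,
) -> np.ndarray:
    """Per-pair ML branch lengths under fitted shared rate parameters.

    Distances at the optimizer bound are returned as ``inf`` (saturated).
    """
    pi = np.asarray(params.pi)
    Q = tn93_rate_matrix(pi, params.kappa1, params.kappa2)
    lam, A, B = _eigen_reversible(Q, pi)
    Fs = np.stack([_pair_counts(seqs[i], seqs[j]) for i, j in pairs])
    Fs = (Fs + Fs.transpose(0, 2, 1)) / 2.0
    d_hat, _ = _profile_distances(lam, A, B, pi, Fs)
    d_hat = np.where(d_hat > 0.99 * _D_MAX, math.inf, d_hat)
    # identical pairs: the profile bottoms out near the lower bound
    ident = np.array(
        [np.trace(F) == F.sum() for F in Fs], dtype=bool
    )
    d_hat = np.where(ident, 0.0, d_hat)
    return d_hat


# ---------------------------------------------------------------------------
# public distance API


def distance(
    a: "str | SeqRecordNT",
    b: "str | SeqRecordNT",
    model: "DistanceModel | str" = "mcl_composite",
    aln_context: "AlignmentSet | None" = None,
) -> float:
    """Evolutionary distance between two aligned sequences (subs/site).

    For ``mcl_composite`` the shared rate parameters are fitted over
    ``aln_context`` when given, otherwise over the two sequences alone.
    Saturated estimates are returned as ``math.inf``.
    """
    model = as_model(model)
    sa, sb = _as_seq(a), _as_seq(b)
    cmp_ = compare_pair(sa, sb)
    if cmp_.identical == cmp_.compared:
        return 0.0
    if model.name == "p":
        return cmp_.p_distance
    if model.name == "jc69":
        return _jc69(cmp_.p_distance)
    if model.name == "k2p":
        n = cmp_.compared
        return _k2p(cmp_.transitions / n, cmp_.transversions / n)
    if model.name == "tn93":
        return _tn93(cmp_, sa, sb)
    # mcl_composite
    if aln_context is not None:
        seqs = [r.seq for r in aln_context.records]
        params = fit_mcl(seqs)
        seqs = seqs + [sa, sb]
        pair = [(len(seqs) - 2, len(seqs) - 1)]
        return float(mcl_distances(seqs, pair, params)[0])
    params = fit_mcl([sa, sb])
    return float(mcl_distances([sa, sb], [(0, 1)], params)[0])


@dataclass
class DistanceMatrix:
    """A labeled symmetric distance matrix.

    ``inf`` entries mark saturated pairs; they are listed in
    ``saturated_pairs`` and rejected by tree building.
    """

    labels: list[str]
    values: np.ndarray
    model: DistanceModel = field(default_factory=DistanceModel)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("diagonal must be zero")
        finite = np.isfinite(self.values)
        if not np.allclose(
            np.where(finite, self.values, 0.0),
            np.where(finite.T, self.values.T, 0.0),
        ):
            raise ValueError("matrix must be symmetric")
        with np.errstate(invalid="ignore"):
            if np.any(self.values[finite] < 0):
                raise ValueError("distances must be nonnegative")

    @property
    def saturated_pairs(self) -> list[tuple[str, str]]:
        out = []
        n = len(self.labels)
        for i in range(n):
            for j in range(i + 1, n):
                if not np.isfinite(self.values[i, j]):
                    out.append((self.labels[i], self.labels[j]))
        return out

    def get(self, a: str, b: str) -> float:
        return float(
            self.values[self.labels.index(a), self.labels.index(b)]
        )

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for label, row in zip(self.labels, self.values):
                fh.write(label + "\t" + "\t".join(f"{v:.9g}" for v in row) + "\n")

    @classmethod
    def read_tsv(cls, path: str | Path, model: "DistanceModel | str" = "p") -> "DistanceMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
            rows = []
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                rows.append([float(x) for x in parts[1:]])
        return cls(labels=header, values=np.array(rows), model=as_model(model))

    def write_mega(self, path: str | Path) -> None:
        """Lower-triangle text export in the style of MEGA distance tables."""
        with open(path, "w") as fh:
            for i, label in enumerate(self.labels):
                cells = "\t".join(f"{self.values[i, j]:.4f}" for j in range(i))
                fh.write(f"[{i + 1}] {label}\t{cells}\n")


def distance_matrix(
    aln: AlignmentSet, model: "DistanceModel | str" = "mcl_composite"
) -> DistanceMatrix:
    """All-pairs distances under pairwise deletion.

    Raises :class:`ComparisonError` listing any pair with no comparable
    sites. Saturated pairs are kept as ``inf`` and flagged on the result.
    """
    model = as_model(model)
    ids = aln.ids
    n = len(ids)
    if n < 2:
        raise ComparisonError("need at least 2 sequences")
    seqs = [r.seq for r in aln.records]
    values = np.zeros((n, n))
    undefined: list[tuple[str, str]] = []
    if model.name == "mcl_composite":
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
        try:
            params = fit_mcl(seqs, pairs)
        except ComparisonError as err:
            raise ComparisonError(f"undefined pair(s): {err}") from err
        d = mcl_distances(seqs, pairs, params)
        for (i, j), dij in zip(pairs, d):
            values[i, j] = values[j, i] = dij
    else:
        for i in range(n):
            for j in range(i + 1, n):
                try:
                    dij = distance(seqs[i], seqs[j], model)
                except ComparisonError:
                    undefined.append((ids[i], ids[j]))
                    continue
                values[i, j] = values[j, i] = dij
        if undefined:
            raise ComparisonError(f"undefined pair(s): {undefined}")
    return DistanceMatrix(labels=list(ids), values=values, model=model)
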