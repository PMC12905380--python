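"""Non-negative signature refitting with strict backward elimination.

A mutation catalog (a 96-channel count spectrum) is modelled as a non-negative
mixture of reference signatures. ``nnls_fit`` solves the constrained
least-squares problem; ``strict_refit`` then removes signatures one at a time,
smallest contribution first, refitting after each removal, and stops when the
cosine similarity of the reconstruction to the observed spectrum has dropped by
more than ``max_delta`` relative to the initial all-signature fit. This mirrors
the strict-refitting procedure commonly used to avoid attributing a catalog to
implausibly many signatures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.optimize


@dataclass
class SignatureMatrix:
    """A 96 x K matrix of per-channel probabilities, one column per signature.

    Columns must be non-negative and sum to 1 (within 1e-6 after any
    renormalization applied by the reader).
    """

    matrix: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.names = list(self.names)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 96:
            raise ValueError(f"signature matrix must be 96 x K, got {self.matrix.shape}")
        if self.matrix.shape[1] != len(self.names):
            raise ValueError("number of names does not match number of columns")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate signature names")
        if np.any(self.matrix < 0):
            raise ValueError("signature matrix has negative entries")
        colsums = self.matrix.sum(axis=0)
        if np.any(np.abs(colsums - 1.0) > 1e-6):
            bad = [self.names[i] for i in np.flatnonzero(np.abs(colsums - 1.0) > 1e-6)]
            raise ValueError(f"signature columns do not sum to 1: {bad}")

    @property
    def n_signatures(self) -> int:
        return self.matrix.shape[1]

    def column(self, name: str) -> np.ndarray:
        try:
            j = self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown signature name: {name!r}") from None
        return self.matrix[:, j]

    def subset(self, names: list[str]) -> "SignatureMatrix":
        idx = [self.names.index(n) for n in names]
        return SignatureMatrix(self.matrix[:, idx], [self.names[i] for i in idx])


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine similarity of two non-negative spectra; 0 if either is zero."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("cosine_similarity expects non-negative spectra")
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def nnls_fit(spectrum: np.ndarray, signatures: SignatureMatrix | np.ndarray) -> np.ndarray:
    """Non-negative least-squares contributions of each signature.

    Minimizes ||spectrum - M x||_2 subject to x >= 0. Contributions are in
    mutation-count units when the spectrum holds counts.
    """
    m = signatures.matrix if isinstance(signatures, SignatureMatrix) else np.asarray(signatures, float)
    if m.ndim != 2 or m.shape[1] == 0:
        raise ValueError("empty signature set")
    y = np.asarray(spectrum, dtype=float)
    if y.shape != (m.shape[0],):
        raise ValueError(f"spectrum length {y.shape} does not match matrix rows {m.shape[0]}")
    x, _ = scipy.optimize.nnls(m, y)
    return x


@dataclass
class RefitResult:
    """Outcome of a strict refit.

    ``contributions`` is aligned to ``names`` and holds zeros for removed
    signatures; ``removal_trace`` lists (removed name, cosine similarity after
    that removal) in removal order.
    """

    names: list[str]
    contributions: np.ndarray
    reconstruction: np.ndarray
    cosine: float
    initial_cosine: float
    removal_trace: list[tuple[str, float]] = field(default_factory=list)

    def contribution(self, name: str) -> float:
        return float(self.contributions[self.names.index(name)])

    @property
    def retained(self) -> list[str]:
        return [n for n, c in zip(self.names, self.contributions) if c > 0]


def strict_refit(
    spectrum: np.ndarray,
    signatures: SignatureMatrix,
    max_delta: float = 0.08,
    per_step: bool = False,
) -> RefitResult:
    """Strict signature refit by backward elimination.

    Fits all signatures, then repeatedly removes the active signature with the
    smallest contribution (ties broken toward the later column) and refits.
    A removal is undone, and elimination stops, when it would lower the cosine
    similarity of the reconstruction by more than ``max_delta`` relative to
    the initial all-signature fit (or to the previous accepted step when
    ``per_step`` is true). Signatures with zero contribution are always
    removable.
    """
    if not 0.0 <= max_delta <= 1.0:
        raise ValueError("max_delta must lie in [0, 1]")
    y = np.asarray(spectrum, dtype=float)
    m = signatures.matrix

    active = list(range(signatures.n_signatures))
    x = nnls_fit(y, m)
    recon = m @ x
    sim_init = cosine_similarity(y, recon)
    sim_cur = sim_init
    trace: list[tuple[str, float]] = []

    x_active = x.copy()
    while active:
        # smallest contribution among active; tie -> later column
        sub = x_active[active]
        best = np.flatnonzero(sub == sub.min())
        j_local = int(best[-1])
        j = active[j_local]
        trial = [k for k in active if k != j]
        if trial:
            xt_sub = nnls_fit(y, m[:, trial])
            xt = np.zeros_like(x_active)
            xt[trial] = xt_sub
            recon_t = m @ xt
            sim_t = cosine_similarity(y, recon_t)
        else:
            xt = np.zeros_like(x_active)
            recon_t = np.zeros_like(y)
            sim_t = 0.0
        reference = sim_cur if per_step else sim_init
        if x_active[j] > 0 and reference - sim_t > max_delta:
            break
        active = trial
        x_active = xt
        recon = recon_t
        sim_cur = sim_t
        trace.append((signatures.names[j], sim_t))

    return RefitResult(
        names=list(signatures.names),
        contributions=x_active,
        reconstruction=recon,
        cosine=sim_cur,
        initial_cosine=sim_init,
        removal_trace=trace,
    )
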