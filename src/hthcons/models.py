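"""Time-reversible 20-state amino-acid substitution models.

A model is a pair (stationary frequencies pi, symmetric exchangeability R)
assembled into a rate matrix Q with q_ij = R_ij * pi_j, normalised so one
unit of branch length equals one expected substitution per site.  Transition
matrices exp(Qt) are computed through the symmetric similarity transform
S = D^{1/2} Q D^{-1/2} (D = diag(pi)), whose real spectrum makes the
exponential numerically stable at any branch length.
"""

from __future__ import annotations

import math

import numpy as np

from .records import AMINO_ACIDS

N_STATES = 20


class ModelError(ValueError):
    pass


class SubstitutionModel:
    """Reversible amino-acid substitution model.

    Parameters
    ----------
    pi:
        Stationary frequencies, length 20 in alphabetical residue order;
        strictly positive, normalised to sum 1.
    exchangeability:
        Symmetric non-negative 20x20 matrix of relative rates (diagonal
        ignored).  ``None`` means equal exchangeabilities (Poisson-type
        model).
    name:
        Free-text label used in reports.
    """

    def __init__(
        self,
        pi: np.ndarray | None = None,
        exchangeability: np.ndarray | None = None,
        name: str = "custom",
        rate_normalizer: float | None = None,
    ):
        if pi is None:
            pi = np.full(N_STATES, 1.0 / N_STATES)
        pi = np.asarray(pi, dtype=float)
        if pi.shape != (N_STATES,):
            raise ModelError(f"pi must have length {N_STATES}")
        if np.any(pi <= 0) or not np.all(np.isfinite(pi)):
            raise ModelError("stationary frequencies must be finite and > 0")
        pi = pi / pi.sum()

        if exchangeability is None:
            R = np.ones((N_STATES, N_STATES))
        else:
            R = np.asarray(exchangeability, dtype=float)
            if R.shape != (N_STATES, N_STATES):
                raise ModelError("exchangeability must be 20x20")
            if not np.allclose(R, R.T):
                raise ModelError("exchangeability must be symmetric")
            if np.any(R < 0):
                raise ModelError("exchangeability entries must be >= 0")
        R = R.copy()
        np.fill_diagonal(R, 0.0)

        Q = R * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        # normalise to 1 expected substitution / site / unit branch length;
        # a derived model (boosted stationary frequencies) instead inherits
        # its parent's normaliser so the constraint reshapes preferences
        # without rescaling the clock
        mu = -float(np.dot(pi, np.diag(Q)))
        if mu <= 0:
            raise ModelError("degenerate rate matrix (no substitutions)")
        self._raw_mu = mu
        self._divisor = rate_normalizer if rate_normalizer is not None else mu
        Q /= self._divisor

        self.name = name
        self.pi = pi
        self.exchangeability = R
        self.Q = Q

        d = np.sqrt(pi)
        S = (Q * d[:, None]) / d[None, :]
        S = 0.5 * (S + S.T)  # enforce exact symmetry
        w, V = np.linalg.eigh(S)
        self._eigvals = w
        self._V = V
        self._d = d
        self._cache: dict[float, np.ndarray] = {}

    def transition(self, t: float) -> np.ndarray:
        """Transition matrix P(t); rows are 'from', columns 'to'."""
        if t < 0 or not math.isfinite(t):
            raise ModelError(f"branch length must be finite and >= 0, got {t}")
        P = self._cache.get(t)
        if P is not None:
            return P
        if t == 0.0:
            P = np.eye(N_STATES)
            self._cache[t] = P
            return P
        w, V, d = self._eigvals, self._V, self._d
        with np.errstate(all="ignore"):
            E = V * np.exp(w * t)[None, :]
            P = (E @ V.T) * (d[None, :] / d[:, None])
        if not np.all(np.isfinite(P)):
            # extreme stationary frequencies (e.g. a hard site constraint)
            # overflow the similarity transform; fall back to a direct
            # matrix exponential
            from scipy.linalg import expm

            P = expm(self.Q * t)
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        if len(self._cache) < 4096:
            self._cache[t] = P
        return P

    def boosted(self, target: str, lam: float) -> "SubstitutionModel":
        """Model with the target residue's stationary frequency boosted.

        pi'_a is proportional to pi_a * exp(lam * 1[a == target]); the
        exchangeabilities are unchanged.  This is the selection proxy used
        when simulating conserved functional sites.
        """
        if target not in AMINO_ACIDS:
            raise ModelError(f"unknown residue {target!r}")
        if not math.isfinite(lam) or lam < 0:
            raise ModelError(f"lambda must be finite and >= 0, got {lam}")
        boost = np.ones(N_STATES)
        boost[AMINO_ACIDS.index(target)] = math.exp(lam)
        # keep the parent's clock: normalise by the parent's divisor so the
        # constraint reshapes stationary preferences without rescaling time
        return SubstitutionModel(
            pi=self.pi * boost,
            exchangeability=self.exchangeability if self._has_custom_R else None,
            name=f"{self.name}+{target}*{lam:g}",
            rate_normalizer=self._divisor,
        )

    @property
    def _has_custom_R(self) -> bool:
        off = self.exchangeability[~np.eye(N_STATES, dtype=bool)]
        return not np.allclose(off, off[0])

    def __repr__(self) -> str:  # pragma: no cover
        return f"<SubstitutionModel {self.name}>"


def poisson_model() -> SubstitutionModel:
    """Equal-rate, uniform-frequency model (the default)."""
    return SubstitutionModel(name="poisson")


def load_exchangeability(path) -> SubstitutionModel:
    """Load a PAML/WAG-style rate file.

    Expected layout: 19 lower-triangle rows of exchangeabilities followed by
    a line (or lines) of 20 stationary frequencies; '#' comments and blank
    lines ignored.  No established Python reader exists for this small text
    dialect, so it is parsed here.
    """
    values: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            values.extend(float(tok) for tok in line.split())
    n_tri = N_STATES * (N_STATES - 1) // 2
    if len(values) != n_tri + N_STATES:
        raise ModelError(
            f"expected {n_tri} exchangeabilities + {N_STATES} frequencies, "
            f"got {len(values)} numbers"
        )
    R = np.zeros((N_STATES, N_STATES))
    k = 0
    for i in range(1, N_STATES):
        for j in range(i):
            R[i, j] = R[j, i] = values[k]
            k += 1
    pi = np.array(values[n_tri:])
    return SubstitutionModel(pi=pi, exchangeability=R, name="loaded")
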