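"""Amino-acid substitution models.

Built-ins: "proportional" (all exchangeabilities and frequencies equal — the
amino-acid Jukes-Cantor analogue with its closed-form distance), plus the
empirical "dayhoff" and "jtt" replacement models, loaded from packaged
PAML-style plain-text files (lower-triangular exchangeabilities followed by
stationary frequencies, in ARNDCQEGHILKMFPSTWYV order).

The rate matrix is Q_ab = s_ab * pi_b (a != b), diagonal set so rows sum to
zero, normalised so the expected rate at stationarity is one substitution per
site per unit time.  Transition matrices P(t) = exp(Qt) are computed through
the symmetric eigendecomposition available for reversible models.
"""

from __future__ import annotations

from importlib import resources

import numpy as np

AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {c: i for i, c in enumerate(AA_ORDER)}
N_AA = 20


class SubstitutionModel:
    """A reversible 20-state amino-acid replacement model."""

    def __init__(self, name: str, exchangeabilities: np.ndarray,
                 frequencies: np.ndarray):
        S = np.asarray(exchangeabilities, dtype=float)
        pi = np.asarray(frequencies, dtype=float)
        if S.shape != (N_AA, N_AA) or not np.allclose(S, S.T):
            raise ValueError("exchangeability matrix must be symmetric 20x20")
        if pi.shape != (N_AA,) or abs(pi.sum() - 1.0) > 1e-6 or (pi <= 0).any():
            raise ValueError("frequencies must be 20 positive values summing to 1")
        self.name = name
        self.S = S
        self.pi = pi / pi.sum()
        Q = S * self.pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -(self.pi * np.diag(Q)).sum()
        self.Q = Q / mu
        # reversible Q: D^{1/2} Q D^{-1/2} is symmetric -> real eigensystem
        d = np.sqrt(self.pi)
        B = (self.Q * d[:, None]) / d[None, :]
        w, V = np.linalg.eigh((B + B.T) / 2.0)
        self._w = w
        self._U = V / d[:, None]          # P(t) = U diag(exp(wt)) Vt
        self._Vt = (V * d[:, None]).T

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows sum to 1 for any t >= 0."""
        if t < 0:
            raise ValueError("time must be non-negative")
        P = (self._U * np.exp(self._w * t)[None, :]) @ self._Vt
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def __repr__(self) -> str:
        return f"SubstitutionModel({self.name!r})"


def _load_paml(name: str) -> tuple[np.ndarray, np.ndarray]:
    text = resources.files("qsoxphylo.data").joinpath(f"{name}.dat").read_text()
    rows = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    S = np.zeros((N_AA, N_AA))
    for i, ln in enumerate(rows[:19], start=1):
        vals = [float(v) for v in ln.split()]
        if len(vals) != i:
            raise ValueError(f"malformed row {i} in {name}.dat")
        S[i, :i] = vals
    S = S + S.T
    pi = np.array([float(v) for v in rows[19].split()])
    return S, pi


_CACHE: dict[str, SubstitutionModel] = {}


def get_model(name: str) -> SubstitutionModel:
    """Look up a built-in model by name ('proportional', 'dayhoff', 'jtt')."""
    key = name.lower()
    if key in _CACHE:
        return _CACHE[key]
    if key == "proportional":
        S = np.ones((N_AA, N_AA))
        np.fill_diagonal(S, 0.0)
        model = SubstitutionModel("proportional", S, np.full(N_AA, 1.0 / N_AA))
    elif key in ("dayhoff", "jtt"):
        S, pi = _load_paml(key)
        model = SubstitutionModel(key, S, pi)
    else:
        raise ValueError(f"unknown substitution model {name!r}")
    _CACHE[key] = model
    return model


def encode_protein(seq: str) -> np.ndarray:
    """Encode a protein string to model indices; gaps/'X' become -1."""
    return np.array([AA_INDEX.get(c, -1) for c in seq.upper()], dtype=int)
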