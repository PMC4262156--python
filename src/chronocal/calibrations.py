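"""Fossil-calibration prior densities on node ages.

Two families are implemented, both anchored on a fossil-based minimum age
``t_L`` (Ma before present):

``uniform``
    Uniform between a hard minimum ``t_L`` and a soft maximum ``t_U``:
    constant density on ``[t_L, t_U]`` carrying mass ``1 - tail_L - tail_R``,
    zero mass below the minimum when ``tail_L = 0`` (the default), and an
    exponential upper tail above ``t_U`` carrying mass ``tail_R``
    (default 0.025, i.e. 2.5% of the probability may exceed the maximum).
    The tail's decay rate is chosen so the density is continuous at ``t_U``.

``cauchy``
    A Cauchy density truncated at the hard minimum: location
    ``A = t_L * (1 + p)`` and scale ``s = c * t_L``, renormalised over
    ``[t_L, inf)``.  The dimensionless location offset ``p`` sets where the
    divergence is expected relative to the fossil minimum (mode at
    ``t_L * (1 + p)``) and the scale multiplier ``c`` sets how heavy the
    tail of plausible older ages is.

All ages are in Ma, densities per Ma.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "Calibration",
    "load_calibrations",
    "write_calibrations",
]

_FAMILIES = ("uniform", "cauchy")


@dataclass(frozen=True)
class Calibration:
    """A probabilistic age constraint attached to one named clade."""

    node_label: str
    family: str
    t_L: float
    t_U: float | None = None
    tail_L: float = 0.0
    tail_R: float = 0.025
    p: float | None = None
    c: float | None = None

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown calibration family {self.family!r}")
        if not self.t_L > 0:
            raise ValueError("minimum age t_L must be positive")
        if not (0 <= self.tail_L < 0.5 and 0 <= self.tail_R < 0.5):
            raise ValueError("tail masses must lie in [0, 0.5)")
        if self.family == "uniform":
            if self.t_U is None:
                raise ValueError(
                    f"calibration {self.node_label!r}: uniform family needs a "
                    "maximum age t_U"
                )
            if not self.t_U > self.t_L:
                raise ValueError("t_U must exceed t_L")
        else:
            if self.p is None or self.c is None:
                raise ValueError("truncated-Cauchy family needs p and c")
            if not (self.p > 0 and self.c > 0):
                raise ValueError("p and c must be positive")
            if self.tail_L != 0:
                raise ValueError("truncated-Cauchy minimum is hard (tail_L = 0)")

    # -- derived constants -------------------------------------------------

    @property
    def has_upper_bound(self) -> bool:
        return self.family == "uniform"

    def _uniform_consts(self):
        # core height h, upper-tail rate lam_U, lower-tail rate lam_L and the
        # exact normaliser Z (Z != 1 only when tail_L > 0, because the lower
        # tail is truncated at age 0)
        span = self.t_U - self.t_L
        h = (1.0 - self.tail_L - self.tail_R) / span
        lam_U = h / self.tail_R if self.tail_R > 0 else math.inf
        if self.tail_L > 0:
            lam_L = h / self.tail_L
            mass_L = self.tail_L * (1.0 - math.exp(-lam_L * self.t_L))
        else:
            lam_L = math.inf
            mass_L = 0.0
        Z = mass_L + (1.0 - self.tail_L - self.tail_R) + self.tail_R
        return h, lam_U, lam_L, mass_L, Z

    def _cauchy_consts(self):
        A = self.t_L * (1.0 + self.p)
        s = self.c * self.t_L
        # mass of the untruncated Cauchy on [t_L, inf)
        mass = 0.5 + math.atan(self.p / self.c) / math.pi
        return A, s, mass

    # -- density -----------------------------------------------------------

    def pdf(self, t):
        """Density (per Ma) at age(s) ``t``."""
        t = np.asarray(t, dtype=float)
        if self.family == "uniform":
            h, lam_U, lam_L, _, Z = self._uniform_consts()
            out = np.zeros_like(t)
            core = (t >= self.t_L) & (t <= self.t_U)
            out[core] = h
            hi = t > self.t_U
            out[hi] = h * np.exp(-lam_U * (t[hi] - self.t_U))
            if self.tail_L > 0:
                lo = (t > 0) & (t < self.t_L)
                out[lo] = h * np.exp(-lam_L * (self.t_L - t[lo]))
            return out / Z
        A, s, mass = self._cauchy_consts()
        out = s / (math.pi * mass * ((t - A) ** 2 + s**2))
        return np.where(t >= self.t_L, out, 0.0)

    def logpdf(self, t):
        with np.errstate(divide="ignore"):
            return np.log(self.pdf(t))

    def cdf(self, t):
        """Cumulative probability at age(s) ``t``."""
        t = np.asarray(t, dtype=float)
        if self.family == "uniform":
            h, lam_U, lam_L, mass_L, Z = self._uniform_consts()
            out = np.empty_like(t)
            lo = t < self.t_L
            if self.tail_L > 0:
                tl = np.clip(t[lo], 0.0, None)
                out[lo] = (
                    self.tail_L
                    * (np.exp(-lam_L * (self.t_L - tl)) - math.exp(-lam_L * self.t_L))
                )
            else:
                out[lo] = 0.0
            core = (t >= self.t_L) & (t <= self.t_U)
            out[core] = mass_L + h * (t[core] - self.t_L)
            hi = t > self.t_U
            out[hi] = (
                mass_L
                + (1.0 - self.tail_L - self.tail_R)
                + self.tail_R * (1.0 - np.exp(-lam_U * (t[hi] - self.t_U)))
            )
            return out / Z
        A, s, mass = self._cauchy_consts()
        lo_cdf = 0.5 + math.atan((self.t_L - A) / s) / math.pi
        out = (0.5 + np.arctan((t - A) / s) / math.pi - lo_cdf) / mass
        return np.clip(np.where(t >= self.t_L, out, 0.0), 0.0, 1.0)

    def quantile(self, q):
        """Inverse cdf; ``quantile(cdf(t)) == t`` on the support."""
        q = np.asarray(q, dtype=float)
        if np.any((q < 0) | (q > 1)):
            raise ValueError("quantile level must lie in [0, 1]")
        if self.family == "uniform":
            h, lam_U, lam_L, mass_L, Z = self._uniform_consts()
            qz = q * Z
            out = np.empty_like(qz)
            lo = qz < mass_L
            if self.tail_L > 0:
                eL = math.exp(-lam_L * self.t_L)
                out[lo] = self.t_L + np.log(qz[lo] / self.tail_L + eL) / lam_L
            else:
                out[lo] = self.t_L  # unreachable when mass_L == 0
            core_top = mass_L + (1.0 - self.tail_L - self.tail_R)
            core = (qz >= mass_L) & (qz <= core_top)
            out[core] = self.t_L + (qz[core] - mass_L) / h
            hi = qz > core_top
            frac = np.clip((qz[hi] - core_top) / self.tail_R, 0.0, 1.0)
            with np.errstate(divide="ignore"):
                out[hi] = self.t_U - np.log1p(-frac) / lam_U
            return out
        A, s, mass = self._cauchy_consts()
        lo_cdf = 0.5 + math.atan((self.t_L - A) / s) / math.pi
        out = A + s * np.tan(math.pi * (q * mass + lo_cdf - 0.5))
        out = np.where(q <= 0.0, self.t_L, out)
        return np.where(q >= 1.0, np.inf, np.maximum(out, self.t_L))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """``n`` i.i.d. draws by inverse-cdf sampling."""
        if n < 1:
            raise ValueError("n must be >= 1")
        return self.quantile(rng.random(n))

    def with_family(self, **kw) -> "Calibration":
        """Copy with replaced fields (e.g. switch family or (p, c))."""
        return replace(self, **kw)


_COLUMNS = ["node_label", "family", "t_L", "t_U", "tail_L", "tail_R", "p", "c"]


def load_calibrations(path) -> list[Calibration]:
    """Read a calibration table (TSV with the standard columns)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("node_label", "family", "t_L") if c not in df.columns]
    if missing:
        raise ValueError(f"calibration table lacks columns {missing}")
    out = []
    for _, row in df.iterrows():
        def get(col, default=None):
            if col not in df.columns or pd.isna(row[col]):
                return default
            return float(row[col])

        out.append(
            Calibration(
                node_label=str(row["node_label"]),
                family=str(row["family"]),
                t_L=float(row["t_L"]),
                t_U=get("t_U"),
                tail_L=get("tail_L", 0.0),
                tail_R=get("tail_R", 0.025),
                p=get("p"),
                c=get("c"),
            )
        )
    return out


def write_calibrations(cals: list[Calibration], path) -> None:
    rows = [
        {
            "node_label": c.node_label,
            "family": c.family,
            "t_L": c.t_L,
            "t_U": c.t_U,
            "tail_L": c.tail_L,
            "tail_R": c.tail_R,
            "p": c.p,
            "c": c.c,
        }
        for c in cals
    ]
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, sep="\t", index=False)
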