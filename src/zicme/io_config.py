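"""Run configuration, CSV/JSON writers, logging, and analytic test fixtures.

The config format is deliberately plain ``key=value`` lines ('#' comments
allowed); no nesting is needed for a five-constant model.  CSV output keeps
17 significant digits so written distributions round-trip losslessly.
"""

from __future__ import annotations

import json
import logging
import math
import sys
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import gammaln

from .model import Distribution, KineticParameters

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "make_fixture_pmf",
    "write_distribution_csv",
    "read_distribution_csv",
    "write_json_summary",
    "setup_logging",
]

logger = logging.getLogger("zicme")

_REQUIRED = ("k1", "k2", "k3", "k4", "V")
_DEFAULTS = {
    "psi": 10,
    "xmax": None,  # None = auto (3 V xbar rule)
    "tol": 1e-10,
    "seed": 0,
    "engine": "exact",
    "output": None,
}


@dataclass(frozen=True)
class RunConfig:
    """Validated bundle of kinetic parameters and solver settings."""

    params: KineticParameters
    psi: int = 10
    xmax: int | None = None
    tol: float = 1e-10
    seed: int = 0
    engine: str = "exact"
    output: str | None = None

    def __post_init__(self):
        if self.engine not in ("exact", "zi"):
            raise ValueError(f"engine must be 'exact' or 'zi', got {self.engine!r}")
        if self.psi < 1:
            raise ValueError(f"psi must be >= 1, got {self.psi}")
        if self.tol <= 0:
            raise ValueError(f"tol must be positive, got {self.tol}")

    def to_dict(self) -> dict:
        d = {k: getattr(self.params, k) for k in _REQUIRED}
        d.update(
            psi=self.psi, xmax=self.xmax, tol=self.tol,
            seed=self.seed, engine=self.engine, output=self.output,
        )
        return d


def load_config(path) -> RunConfig:
    """Parse a key=value config file into a validated RunConfig.

    Unknown keys are rejected with a descriptive error; missing kinetic
    constants likewise.  Values for xmax/output may be the literal ``none``.
    """
    path = Path(path)
    raw: dict[str, str] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected key=value, got {line!r}")
        key, val = (s.strip() for s in line.split("=", 1))
        if key in raw:
            raise ValueError(f"{path}:{lineno}: duplicate key {key!r}")
        raw[key] = val

    known = set(_REQUIRED) | set(_DEFAULTS)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    missing = [k for k in _REQUIRED if k not in raw]
    if missing:
        raise ValueError(f"{path}: missing required keys {missing}")

    def num(key, conv=float):
        try:
            return conv(raw[key])
        except ValueError as exc:
            raise ValueError(f"{path}: key {key!r}: non-numeric value {raw[key]!r}") from exc

    params = KineticParameters(**{k: num(k) for k in _REQUIRED})
    kw = {}
    for key, default in _DEFAULTS.items():
        if key not in raw:
            kw[key] = default
        elif key == "engine":
            kw[key] = raw[key]
        elif key == "output":
            kw[key] = None if raw[key].lower() == "none" else raw[key]
        elif key == "xmax":
            kw[key] = None if raw[key].lower() == "none" else num(key, lambda s: int(float(s)))
        elif key in ("psi", "seed"):
            kw[key] = num(key, lambda s: int(float(s)))
        else:
            kw[key] = num(key)
    return RunConfig(params=params, **kw)


def save_config(cfg: RunConfig, path) -> None:
    """Write a RunConfig as key=value lines; load_config round-trips it."""
    lines = []
    for k, v in cfg.to_dict().items():
        if isinstance(v, float):
            lines.append(f"{k}={v!r}")
        else:
            lines.append(f"{k}={'none' if v is None else v}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# fixtures with analytically known moments and entropy
# ---------------------------------------------------------------------------


def make_fixture_pmf(kind: str, **shape) -> Distribution:
    """Normalized pmfs with closed-form moments/entropy for unit tests.

    kinds: ``delta(at)``, ``uniform(n)``, ``two_point(a, b, w)``,
    ``geometric(ratio, xmax)``, ``poisson(mean, xmax)``,
    ``two_peak(mu1, mu2, w, xmax)`` (mixture of two Poissons).
    """
    if kind == "delta":
        at = int(shape["at"])
        p = np.zeros(at + 1)
        p[at] = 1.0
        return Distribution.from_p(p)
    if kind == "uniform":
        n = int(shape["n"])
        return Distribution.from_p(np.full(n, 1.0 / n))
    if kind == "two_point":
        a, b = int(shape["a"]), int(shape["b"])
        w = float(shape.get("w", 0.5))
        p = np.zeros(max(a, b) + 1)
        p[a], p[b] = w, 1.0 - w
        return Distribution.from_p(p)
    if kind == "geometric":
        r = float(shape["ratio"])
        xmax = int(shape["xmax"])
        if not 0 < r < 1:
            raise ValueError("geometric ratio must be in (0, 1)")
        X = np.arange(xmax + 1)
        return Distribution(X * math.log(r))
    if kind == "poisson":
        mean = float(shape["mean"])
        xmax = int(shape["xmax"])
        X = np.arange(xmax + 1)
        return Distribution(X * math.log(mean) - gammaln(X + 1) - mean)
    if kind == "two_peak":
        mu1, mu2 = float(shape["mu1"]), float(shape["mu2"])
        w = float(shape.get("w", 0.5))
        xmax = int(shape["xmax"])
        X = np.arange(xmax + 1)
        p1 = np.exp(X * math.log(mu1) - gammaln(X + 1) - mu1)
        p2 = np.exp(X * math.log(mu2) - gammaln(X + 1) - mu2)
        return Distribution.from_p(w * p1 + (1 - w) * p2)
    raise ValueError(f"unknown fixture kind {kind!r}")


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_distribution_csv(dist: Distribution, path) -> None:
    """CSV columns X,p,log_p at 17 significant digits (lossless doubles)."""
    with open(path, "w") as fh:
        fh.write("X,p,log_p\n")
        for x, (p, lp) in enumerate(zip(dist.p, dist.log_p)):
            fh.write(f"{x},{p:.17g},{lp:.17g}\n")


def read_distribution_csv(path) -> Distribution:
    log_p = np.loadtxt(path, delimiter=",", skiprows=1, usecols=2)
    return Distribution(np.atleast_1d(log_p), normalized=True)


def write_json_summary(payload: dict, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(payload, indent=2, default=default) + "\n")


def setup_logging(level=logging.INFO) -> None:
    """Console logging with a run-header format used by every CLI entry."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    )
    root = logging.getLogger("zicme")
    if not root.handlers:
        root.addHandler(handler)
    root.setLevel(level)
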