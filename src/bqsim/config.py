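"""Simulation configuration: parameters, validation and flat YAML round-trip.

All rates are per model time step (``dt`` = 1 step by default); biomass and
concentrations are femtograms of carbon per individual / per lattice box.
``steps_per_hour`` maps model steps onto wall-clock hours for protocols that
are specified in hours (e.g. a 12 h nutrient shut-off).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml


class ConfigError(ValueError):
    """A configuration value violates a model invariant."""


@dataclass
class SimConfig:
    """All parameters of one simulation run.

    Parameters
    ----------
    alpha
        Function cost: fraction of biomass spent per unit time to produce
        one public good.  Production of a carried good is ``alpha * X * dt``.
    beta
        Required-to-produced ratio per public good; ``1 - beta`` is the
        redundant (shareable) fraction of production.  A scalar applies to
        all three goods; a triple sets per-good values.
    mut
        Per-function probability that a daughter cell loses a carried
        function at division.
    g_max, d_max
        Maximum per-step growth and death rates of the Monod growth law.
    base_death_rate
        Basal per-step probability that a cell dies regardless of biomass
        (dilution / age turnover); keeps birth-death turnover going at the
        crowded steady state. 0 disables it.
    X0
        Reference biomass (fg); cells start at ``X0``, divide near
        ``division_factor * X0`` and die below ``death_factor * X0``.
    eps_amplitude
        Half-width of the uniform threshold noise epsilon (fg), drawn fresh
        at every division/death check.
    K_S
        Substrate half-saturation constant (fg per box).
    K_P
        Public-good half-saturation constant (fg per box), used only when
        ``benefit_mode == "monod"``.
    D_S, D_P
        Diffusion coefficients (box^2 per step) of substrate and goods.
    supply_rate
        Substrate influx per box per step (fg).
    substrate_decay, goods_decay
        First-order per-step loss rates of the fields; keep concentrations
        bounded where nothing consumes them.
    yield_S
        Biomass produced per fg substrate consumed.
    benefit_mode
        ``"fulfillment"`` (default): the growth benefit is
        ``d_max * min_j s_j`` with ``s_j`` the fraction of the per-step
        requirement of non-carried good j actually taken up (1 for carried
        goods).  ``"monod"``: ``s_j = P_j / (K_P + P_j)`` for non-carried
        goods instead.
    neighborhood
        ``"von_neumann"`` (4 adjacent boxes, default) or ``"moore"`` (8)
        for daughter placement.
    well_mixed
        Replace diffusion by even redistribution of each field every step.
    """

    alpha: float = 0.001
    beta: float | tuple[float, float, float] = 0.8
    mut: float = 1e-5
    g_max: float = 0.2
    d_max: float = 0.1
    base_death_rate: float = 1e-3
    X0: float = 150.0
    eps_amplitude: float = 7.5
    K_S: float = 1.0
    K_P: float = 0.1
    D_S: float = 0.2
    D_P: float = 0.1
    supply_rate: float = 0.4
    substrate_decay: float = 0.005
    goods_decay: float = 0.005
    yield_S: float = 1.0
    dt: float = 1.0
    dx: float = 1.0
    L: int = 100
    n_steps: int = 150_000
    seed: int = 0
    division_factor: float = 2.0
    death_factor: float = 0.2
    steps_per_hour: int = 80
    benefit_mode: str = "fulfillment"
    neighborhood: str = "von_neumann"
    well_mixed: bool = False

    def __post_init__(self) -> None:
        self.validate()

    # -- derived quantities -------------------------------------------------

    @property
    def beta_vec(self) -> np.ndarray:
        """Per-good beta as a length-3 float array."""
        b = self.beta
        if np.isscalar(b):
            return np.full(3, float(b))
        return np.asarray(b, dtype=float)

    @property
    def division_threshold(self) -> float:
        return self.division_factor * self.X0

    @property
    def death_threshold(self) -> float:
        return self.death_factor * self.X0

    @property
    def biomass_cap(self) -> float:
        # contact-inhibited cells stop accumulating at twice the division size
        return 2.0 * self.division_factor * self.X0

    def stability_lambda(self) -> float:
        """Largest diffusion stencil weight D*dt/dx^2 across the fields."""
        return max(self.D_S, self.D_P) * self.dt / self.dx**2

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        bvec = self.beta_vec
        if bvec.shape != (3,):
            raise ConfigError("beta must be a scalar or a triple")
        if self.alpha < 0:
            raise ConfigError(f"alpha must be >= 0, got {self.alpha}")
        if np.any(bvec <= 0) or np.any(bvec > 1):
            raise ConfigError(f"beta must satisfy 0 < beta <= 1, got {self.beta}")
        if not 0 <= self.mut <= 1:
            raise ConfigError(f"mut must be in [0, 1], got {self.mut}")
        if self.L < 2:
            raise ConfigError(f"L must be >= 2, got {self.L}")
        if self.dt <= 0:
            raise ConfigError(f"dt must be > 0, got {self.dt}")
        if self.g_max < 0 or self.d_max < 0:
            raise ConfigError("g_max and d_max must be >= 0")
        if not 0 <= self.base_death_rate <= 1:
            raise ConfigError("base_death_rate must be in [0, 1]")
        if self.X0 <= 0:
            raise ConfigError(f"X0 must be > 0, got {self.X0}")
        if self.K_S <= 0 or self.K_P <= 0:
            raise ConfigError("K_S and K_P must be > 0")
        if min(self.D_S, self.D_P) < 0:
            raise ConfigError("diffusion coefficients must be >= 0")
        lam = self.stability_lambda()
        if lam > 0.25 + 1e-12:
            raise ConfigError(
                f"explicit diffusion unstable: D*dt/dx^2 = {lam:.4g} > 1/4"
            )
        if self.benefit_mode not in ("fulfillment", "monod"):
            raise ConfigError(f"unknown benefit_mode {self.benefit_mode!r}")
        if self.neighborhood not in ("von_neumann", "moore"):
            raise ConfigError(f"unknown neighborhood {self.neighborhood!r}")
        if self.seed < 0 or self.seed >= 2**31:
            raise ConfigError("seed must be in [0, 2^31)")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if not np.isscalar(d["beta"]):
            d["beta"] = [float(x) for x in d["beta"]]
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        d = dict(data)
        if "beta" in d and isinstance(d["beta"], (list, tuple)):
            d["beta"] = tuple(float(x) for x in d["beta"])
        return cls(**d)

    def replace(self, **changes) -> "SimConfig":
        return dataclasses.replace(self, **changes)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "SimConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} is not a key-value mapping")
        return cls.from_dict(data)

    def content_hash(self) -> str:
        """Stable short hash of the resolved configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


load_config = SimConfig.load
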