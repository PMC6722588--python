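"""Synthetic per-infructescence community data with controllable structure.

The generator emulates the statistical design of an elevation-stratified
infructescence survey: a fixed set of host plants each contributes a
number of sampling units (infructescences) per elevation stratum, insect
species carry a dominance-skewed species-abundance distribution, each
insect concentrates its interactions inside a planted host block
(modularity / specialization dial ``kappa``), and the species pool turns
over along the elevation gradient (dial ``tau``).  Everything is
reproducible from the configuration seed.

Species totals come from deterministic lognormal quantiles (a ranked
expected abundance curve) rather than random draws, so the dominance
structure is a property of the configuration, not of the seed; the
randomness enters through multinomial allocation of individuals to
hosts, strata and units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .webs import InteractionWeb, RecordTable, ValidationError

__all__ = ["SyntheticConfig", "generate_community", "reference_survey_config", "planted_web"]

_ELEVATION_NAMES = ("low", "mid", "high")


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic infructescence survey.

    Defaults mirror the Los Tuxtlas survey design: 8 hosts, 34 insect
    species, 250 infructescences split 123/94/33 across three elevation
    strata, 16,120 individuals, strong dominance (the four most abundant
    species hold roughly three quarters of all individuals) and high
    within-block concentration.
    """

    n_hosts: int = 8
    n_insects: int = 34
    n_elevations: int = 3
    units_per_elevation: tuple[int, ...] = (123, 94, 33)
    total_individuals: int = 16_120
    n_blocks: int = 4
    kappa: float = 0.9  # within-block interaction concentration, in [0, 1]
    abundance_sigma: float = 2.0  # lognormal shape of the ranked SAD
    tau: float = 0.5  # fraction of the species pool replaced per stratum step
    seed: int = 0
    insect_blocks: tuple[int, ...] | None = field(default=None)
    host_blocks: tuple[int, ...] | None = field(default=None)

    def __post_init__(self) -> None:
        if min(self.n_hosts, self.n_insects, self.n_elevations, self.n_blocks) < 1:
            raise ValidationError("all dimensions must be >= 1")
        if len(self.units_per_elevation) != self.n_elevations:
            raise ValidationError("units_per_elevation length must equal n_elevations")
        if any(u < 1 for u in self.units_per_elevation):
            raise ValidationError("every stratum needs at least one sampling unit")
        if not (0.0 <= self.kappa <= 1.0 and 0.0 <= self.tau <= 1.0):
            raise ValidationError("kappa and tau must lie in [0, 1]")
        if self.n_blocks > min(self.n_hosts, self.n_insects):
            raise ValidationError("more blocks than species on one side")
        if self.total_individuals < 1:
            raise ValidationError("need at least one individual")


def _ranked_lognormal_weights(s: int, sigma: float) -> np.ndarray:
    """Expected abundances of a rank-ordered lognormal SAD (descending)."""
    from scipy.stats import norm

    ranks = (np.arange(s) + 0.5) / s
    return np.exp(sigma * norm.ppf(1.0 - ranks))


def _split_even(total: int, parts: int) -> np.ndarray:
    """Deterministic near-even integer split of ``total`` into ``parts``."""
    base = np.full(parts, total // parts, dtype=np.int64)
    base[: total % parts] += 1
    return base


def _elevation_pools(s: int, n_elev: int, tau: float) -> list[np.ndarray]:
    """Ranked-pool windows implementing turnover at rate ``tau``.

    Species are laid out along the gradient by index; each stratum sees a
    window of the pool shifted by ``tau`` window-widths per step, so
    tau=0 gives identical pools and tau=1 disjoint adjacent pools.
    """
    if n_elev == 1 or tau == 0.0:
        return [np.arange(s)] * n_elev
    width = max(1, int(round(s / (1.0 + tau * (n_elev - 1)))))
    pools = []
    for e in range(n_elev):
        start = int(round(e * tau * width))
        start = min(start, max(0, s - width))
        pools.append(np.arange(start, min(s, start + width)))
    return pools


def _host_preferences(cfg: SyntheticConfig, insect_blocks: np.ndarray, host_blocks: np.ndarray) -> np.ndarray:
    """Per-insect host-use probabilities: kappa inside the planted block,
    1 - kappa spread uniformly over the remaining hosts."""
    pref = np.zeros((cfg.n_insects, cfg.n_hosts))
    for i in range(cfg.n_insects):
        inside = host_blocks == insect_blocks[i]
        n_in = int(inside.sum())
        n_out = cfg.n_hosts - n_in
        if n_in == 0:
            pref[i] = 1.0 / cfg.n_hosts
        elif n_out == 0:
            pref[i, inside] = 1.0 / n_in
        else:
            pref[i, inside] = cfg.kappa / n_in
            pref[i, ~inside] = (1.0 - cfg.kappa) / n_out
    return pref


def generate_community(cfg: SyntheticConfig) -> tuple[RecordTable, dict]:
    """Draw one synthetic survey; returns records plus ground truth.

    The ground-truth dictionary holds the planted block maps, the
    per-stratum species pools, and the internally aggregated
    insect x host web the records must reproduce exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    S, H, E = cfg.n_insects, cfg.n_hosts, cfg.n_elevations

    species = [f"sp{i + 1:02d}" for i in range(S)]
    hosts = [f"host{h + 1}" for h in range(H)]
    elev_names = list(_ELEVATION_NAMES) if E == 3 else [f"level{e + 1}" for e in range(E)]

    # dominance: ranked weights, assigned to species in a seeded shuffle so
    # gradient position (species index) is independent of abundance rank
    ranked = _ranked_lognormal_weights(S, cfg.abundance_sigma)
    w = np.empty(S)
    w[rng.permutation(S)] = ranked

    insect_blocks = (
        np.asarray(cfg.insect_blocks, dtype=np.int64)
        if cfg.insect_blocks is not None
        else np.arange(S) % cfg.n_blocks
    )
    host_blocks = (
        np.asarray(cfg.host_blocks, dtype=np.int64)
        if cfg.host_blocks is not None
        else np.arange(H) % cfg.n_blocks
    )
    if insect_blocks.size != S or host_blocks.size != H:
        raise ValidationError("block map length mismatch")

    pref = _host_preferences(cfg, insect_blocks, host_blocks)
    pools = _elevation_pools(S, E, cfg.tau)
    units = np.vstack([_split_even(u, H) for u in cfg.units_per_elevation]).T  # hosts x elev

    # allocation law over (species, host, stratum) cells
    q = np.zeros((S, H, E))
    for e in range(E):
        mask = np.zeros(S)
        mask[pools[e]] = 1.0
        q[:, :, e] = (w * mask)[:, None] * pref * units[None, :, e]
    if q.sum() <= 0:
        raise ValidationError("configuration allocates zero probability mass")
    draws = rng.multinomial(cfg.total_individuals, (q / q.sum()).ravel()).reshape(S, H, E)

    rows = []
    for e in range(E):
        for h in range(H):
            n_units = int(units[h, e])
            if n_units == 0:
                continue
            unit_ids = [f"{hosts[h]}-{elev_names[e]}-{k + 1:03d}" for k in range(n_units)]
            for s in range(S):
                n = int(draws[s, h, e])
                if n == 0:
                    continue
                per_unit = rng.multinomial(n, np.full(n_units, 1.0 / n_units))
                for uid, cnt in zip(unit_ids, per_unit):
                    if cnt > 0:
                        rows.append((hosts[h], elev_names[e], uid, species[s], int(cnt)))
    if not rows:
        raise ValidationError("generated community is empty; increase total_individuals")
    records = RecordTable(pd.DataFrame(rows, columns=["host", "elevation", "unit_id", "species", "count"]))

    web_frame = pd.DataFrame(draws.sum(axis=2), index=species, columns=hosts)
    truth = {
        "insect_blocks": dict(zip(species, insect_blocks.tolist())),
        "host_blocks": dict(zip(hosts, host_blocks.tolist())),
        "pools": {elev_names[e]: [species[i] for i in pools[e]] for e in range(E)},
        "web": web_frame,
        "weights": dict(zip(species, w.tolist())),
        "config": cfg,
    }
    return records, truth


def reference_survey_config(seed: int = 0) -> SyntheticConfig:
    """The survey-shaped configuration: 8 hosts, 34 insects, 3 strata,
    250 infructescences (123/94/33), 16,120 individuals, dominance such
    that the four most abundant species hold roughly 70-80% of them."""
    return SyntheticConfig(seed=seed)


def planted_web(cfg: SyntheticConfig) -> InteractionWeb:
    """Convenience: generate and aggregate to the insect x host web."""
    records, _ = generate_community(cfg)
    return records.to_web()
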