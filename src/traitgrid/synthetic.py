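"""Synthetic study worlds with known parameters.

Everything the pipeline ingests can be generated here: a species pool with
realistic egg-elongation and nest-type marginals (about 300 species, mean
elongation near 1.37 with sd 0.07, a 62/33/5 percent cup/dome/cavity mix),
spatially autocorrelated VPD and LAI surfaces (negatively associated, as
dry regions carry sparse canopies), occurrence records whose species niches
track the VPD axis, and assemblage-level responses drawn from a SAR error
process with known coefficients for parameter-recovery tests.

Every output is a pure function of (config, seed); stage sub-streams are
derived from the root seed with fixed offsets so stages can be regenerated
independently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .grids import GridSpec, inverse_project
from .spatial import SpatialWeights

logger = logging.getLogger(__name__)

# fixed stage offsets for sub-stream derivation
_STAGE_SPECIES, _STAGE_ENV, _STAGE_OCC, _STAGE_RESP = 11, 23, 37, 53


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng([stage, int(seed)])


@dataclass(frozen=True)
class SyntheticConfig:
    seed: int = 0
    n_species: int = 300
    nest_type_probs: tuple = (0.62, 0.33, 0.05)  # cup, dome, cavity
    elong_mean: float = 1.37
    elong_sd: float = 0.07
    elong_bounds: tuple = (1.05, 1.70)
    #: additive elongation-mean offsets per nest type (cup, dome, cavity);
    #: cavity nesters lay distinctly rounder eggs
    nest_elong_offsets: tuple = (0.0, 0.0, -0.07)
    family_block: int = 10
    grid: GridSpec = field(default_factory=GridSpec)
    gp_range: float = 300_000.0          # GRF correlation length, metres
    vpd_bounds: tuple = (0.2, 4.5)       # kPa
    lai_bounds: tuple = (0.05, 5.5)
    lai_vpd_corr: float = -0.6
    niche_strength: float = 1.0          # 0 = no trait-environment association
    occupancy_width: float = 3.0         # kPa^2, niche breadth
    max_records_per_cell: int = 3
    events_per_cell: int = 12
    full_occupancy: bool = False
    # assemblage-level response process y = X beta + (I - lam W)^-1 eps
    response_beta: tuple = (1.0, 0.5, -0.3, 0.1)
    response_lambda: float = 0.7
    response_sigma: float = 1.0

    def __post_init__(self):
        if abs(sum(self.nest_type_probs) - 1.0) > 1e-9:
            raise ValueError("nest_type_probs must sum to 1")
        if self.elong_sd <= 0:
            raise ValueError("elong_sd must be positive")


def _truncated_normal(rng, mean, sd, lo, hi, size):
    """Rejection sampling; the truncation is mild so this converges fast."""
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=size)
        keep = draw[(draw >= lo) & (draw <= hi)]
        take = min(keep.size, size - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def generate_species(cfg: SyntheticConfig) -> pd.DataFrame:
    """Species trait table: nest types, elongation, back-solved egg sizes.

    Breadth ~ U(14, 18) mm and length = breadth * elongation, so recomputing
    elongation from the measurements reproduces the sampled values exactly.
    Families are assigned in consecutive blocks to give the random-intercept
    model a grouping structure.
    """
    rng = _stage_rng(cfg.seed, _STAGE_SPECIES)
    n = cfg.n_species
    nest = rng.choice(["cup", "dome", "cavity"], size=n, p=cfg.nest_type_probs)
    offsets = dict(zip(("cup", "dome", "cavity"), cfg.nest_elong_offsets))
    elong = np.empty(n)
    for nest_type, off in offsets.items():
        mask = nest == nest_type
        if mask.any():
            elong[mask] = _truncated_normal(
                rng, cfg.elong_mean + off, cfg.elong_sd, *cfg.elong_bounds,
                size=int(mask.sum()),
            )
    breadth = rng.uniform(14.0, 18.0, size=n)
    length = breadth * elong
    family = [f"fam{(i // cfg.family_block):03d}" for i in range(n)]
    return pd.DataFrame({
        "species_id": [f"sp{i:04d}" for i in range(n)],
        "common_name": [f"Synthetic species {i}" for i in range(n)],
        "family": family,
        "nest_type": nest,
        "egg_length_mm": length,
        "egg_breadth_mm": breadth,
    })


def _grf(rng, ny, nx, range_cells):
    """Standardised Gaussian random field via kernel-smoothed white noise."""
    noise = rng.standard_normal((ny, nx))
    if range_cells > 0:
        noise = gaussian_filter(noise, sigma=range_cells, mode="reflect")
    sd = noise.std()
    if sd == 0:  # pragma: no cover - only for degenerate 1-cell grids
        return noise
    return (noise - noise.mean()) / sd


def _affine_map(z, lo, hi):
    zmin, zmax = z.min(), z.max()
    if zmax == zmin:  # pragma: no cover
        return np.full_like(z, 0.5 * (lo + hi))
    return lo + (z - zmin) / (zmax - zmin) * (hi - lo)


def generate_environment(cfg: SyntheticConfig) -> dict:
    """Spatially autocorrelated VPD and LAI surfaces on the analysis grid.

    Two correlated Gaussian random fields are affinely mapped into the
    configured physical ranges; the LAI field is built to correlate with
    VPD at about ``lai_vpd_corr`` (negative by default: arid cells have
    sparse canopies).
    """
    rng = _stage_rng(cfg.seed, _STAGE_ENV)
    ny, nx = cfg.grid.ny, cfg.grid.nx
    range_cells = cfg.gp_range / cfg.grid.cell_size
    z1 = _grf(rng, ny, nx, range_cells)
    z2 = _grf(rng, ny, nx, range_cells)
    rho = cfg.lai_vpd_corr
    z_lai = rho * z1 + np.sqrt(1.0 - rho**2) * z2
    return {
        "vpd": _affine_map(z1, *cfg.vpd_bounds),
        "lai": _affine_map(z_lai, *cfg.lai_bounds),
    }


def _niche_optima(species: pd.DataFrame, cfg: SyntheticConfig, rng,
                  vpd_lo: float, vpd_hi: float) -> np.ndarray:
    """Per-species VPD niche optimum.

    With positive ``niche_strength`` dome nesters and round-egged species
    are pulled toward the arid (high-VPD) end, which is what produces the
    assemblage-level gradients: proportion domed rising, mean elongation
    falling, with VPD.
    """
    n = len(species)
    u = rng.uniform(0.0, 1.0, size=n)
    s = cfg.niche_strength
    if s != 0.0:
        is_dome = (species["nest_type"] == "dome").to_numpy(dtype=float)
        elong = (species["egg_length_mm"] / species["egg_breadth_mm"]).to_numpy()
        z_round = np.clip((cfg.elong_mean - elong) / cfg.elong_sd, -2.0, 2.0)
        u = u + s * (0.30 * is_dome - 0.15 + 0.10 * z_round)
    u = np.clip(u, 0.02, 0.98)
    return vpd_lo + u * (vpd_hi - vpd_lo)


def generate_occurrences(species: pd.DataFrame, env: dict,
                         cfg: SyntheticConfig) -> pd.DataFrame:
    """Occurrence records (species_id, lon, lat, event_id).

    Cell occupancy is Bernoulli with probability
    logistic(-(vpd_cell - optimum)^2 / width); each occupied cell emits 1 to
    ``max_records_per_cell`` point records at uniform in-cell coordinates
    (inverse-projected to lon/lat) tagged with cell-level sampling-event ids
    so Chao2 completeness can be exercised.
    """
    rng = _stage_rng(cfg.seed, _STAGE_OCC)
    grid = cfg.grid
    vpd_cells = np.asarray(env["vpd"], dtype=float).ravel()  # row-major (iy, ix)
    iy_all, ix_all = np.divmod(np.arange(grid.n_cells), grid.nx)
    optima = _niche_optima(species, cfg, rng, *cfg.vpd_bounds)

    rec_species, rec_ix, rec_iy, rec_event = [], [], [], []
    n_failed = 0
    for si, opt in enumerate(optima):
        if cfg.full_occupancy:
            occupied = np.arange(grid.n_cells)
        else:
            p = 1.0 / (1.0 + np.exp((vpd_cells - opt) ** 2 / cfg.occupancy_width))
            occupied = np.flatnonzero(rng.random(grid.n_cells) < p)
            attempts = 0
            while occupied.size == 0 and attempts < 10:
                occupied = np.flatnonzero(rng.random(grid.n_cells) < p)
                attempts += 1
            if occupied.size == 0:
                n_failed += 1
                continue
        n_rec = rng.integers(1, cfg.max_records_per_cell + 1, size=occupied.size)
        cells = np.repeat(occupied, n_rec)
        rec_species.append(np.full(cells.size, si))
        rec_ix.append(ix_all[cells])
        rec_iy.append(iy_all[cells])
        rec_event.append(rng.integers(0, cfg.events_per_cell, size=cells.size))
    if n_failed:
        logger.warning("%d species occupied no cell after 10 attempts", n_failed)
    if not rec_species:
        return pd.DataFrame(columns=["species_id", "lon", "lat", "event_id"])
    sp = np.concatenate(rec_species)
    ix = np.concatenate(rec_ix)
    iy = np.concatenate(rec_iy)
    ev = np.concatenate(rec_event)
    x0, y0 = grid.origin
    x = x0 + (ix + rng.random(ix.size)) * grid.cell_size
    y = y0 + (iy + rng.random(iy.size)) * grid.cell_size
    lon, lat = inverse_project(x, y, grid.projection)
    ids = species["species_id"].to_numpy()
    return pd.DataFrame({
        "species_id": ids[sp],
        "lon": lon,
        "lat": lat,
        "event_id": [f"e{a}_{b}_{t}" for a, b, t in zip(ix, iy, ev)],
    })


def generate_sar_response(X, weights: SpatialWeights, beta, lam: float,
                          sigma: float, seed: int) -> np.ndarray:
    """Draw y = X beta + (I - lam W)^{-1} eps with eps ~ N(0, sigma^2 I).

    The spatial term uses a linear solve, never an explicit inverse.
    """
    X = np.asarray(X, dtype=float)
    beta = np.asarray(beta, dtype=float)
    rng = _stage_rng(seed, _STAGE_RESP)
    n = X.shape[0]
    W = weights.dense()
    A = np.eye(n) - lam * W
    eps = rng.normal(0.0, sigma, size=n)
    try:
        u = np.linalg.solve(A, eps)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular (I - lambda W) at lambda={lam}") from exc
    return X @ beta + u


def generate_world(cfg: SyntheticConfig) -> dict:
    """Full synthetic study: species, surfaces, occurrences."""
    species = generate_species(cfg)
    env = generate_environment(cfg)
    occurrences = generate_occurrences(species, env, cfg)
    return {"config": cfg, "species": species, "env": env,
            "occurrences": occurrences}


def fixture_config(seed: int = 0, n_species: int = 150) -> SyntheticConfig:
    """Small world (10x10 grid, 150 species) used by unit tests and fixtures."""
    return SyntheticConfig(
        seed=seed,
        n_species=n_species,
        grid=GridSpec(cell_size=100_000.0, origin=(-500_000.0, -4_000_000.0),
                      extent=(10, 10)),
    )


def write_world(world: dict, outdir) -> None:
    """Materialise a world in the CSV/ASCII dialects the ingestion code reads."""
    from pathlib import Path

    from .environment import RasterGeom, write_ascii_grid

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    world["species"].to_csv(outdir / "traits.csv", index=False)
    world["occurrences"].to_csv(outdir / "occurrences.csv", index=False)
    geom = RasterGeom.from_grid(world["config"].grid)
    write_ascii_grid(outdir / "vpd.asc", world["env"]["vpd"], geom)
    write_ascii_grid(outdir / "lai.asc", world["env"]["lai"], geom)
    with open(outdir / "units.txt", "w") as fh:
        fh.write("vpd.asc: kPa\nlai.asc: dimensionless\n")
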