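"""Synthetic inputs for every pipeline stage.

Three generators stand in for the field and hydrodynamic data:

* ``simulate_genotypes`` — multi-site diploid microsatellite panels. Site
  allele frequencies diverge from Dirichlet-drawn ancestral frequencies
  under the Balding-Nichols island model with parameter F (the expected
  F_ST), genets are drawn under Hardy-Weinberg within sites, and ramets are
  replicated with a geometric clone-size law so each site hits its target
  genotypic richness R.
* ``simulate_bay`` — an enclosed rectangular bay with a land border and a
  mouth, bowl-shaped bathymetry, and currents from a double-gyre
  streamfunction (finite-differenced, hence discretely divergence-free)
  plus a spatially uniform sinusoidal tide.
* ``simulate_reproduction`` — per-site seed and spathe densities together
  with clonality targets drawn from a logit-link beta law in log seed
  density and log propagule inflow, so the regression stage has a known
  ground truth to recover.

All generators are deterministic given one integer seed; each component
uses an independent substream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .dispersal import CurrentField, HabitatPatch
from .genotypes import MultilocusGenotype, SampleRecord

__all__ = [
    "SynthConfig",
    "simulate_genotypes",
    "simulate_bay",
    "simulate_reproduction",
]


@dataclass
class SynthConfig:
    """Study-condition defaults: 16 sites of 45 samples at 9 loci with 3-16
    alleles each, moderate differentiation (F about 0.06), clonality spanning
    R 0.18-0.93, and seed densities spanning orders of magnitude."""

    n_sites: int = 16
    n_loci: int = 9
    alleles_per_locus: tuple | None = None  # None -> uniform 3..16
    fst_target: float = 0.06
    samples_per_site: int = 45
    clonality_targets: tuple | None = None  # None -> even spread 0.18..0.93
    clone_dominance: float = 0.3  # geometric clone-size parameter
    # bay
    grid_shape: tuple = (40, 40)
    domain_km: float = 20.0
    field_days: float = 60.0
    n_patches: int = 16
    gyre_strength: float = 250.0  # streamfunction amplitude, m2/s
    tidal_amplitude: float = 0.05  # m/s
    tidal_period_h: float = 12.42
    current_noise: float = 0.0  # m/s std of optional velocity noise
    # regression truth (logit scale on log predictors)
    beta_truth: tuple = (-0.7, 0.25, 0.30)
    phi: float = 30.0
    spathe_noise_sd: float = 0.4
    seed: int = 0

    def __post_init__(self):
        if min(self.n_sites, self.n_loci, self.samples_per_site, self.n_patches) < 1:
            raise ValueError("all counts must be >= 1")
        if not 0.0 <= self.fst_target < 1.0:
            raise ValueError("fst_target must be in [0, 1)")
        if self.clonality_targets is not None:
            if len(self.clonality_targets) != self.n_sites:
                raise ValueError("need one clonality target per site")
            if any(not 0.0 < r <= 1.0 for r in self.clonality_targets):
                raise ValueError("clonality targets must be in (0, 1]")
        if min(self.grid_shape) < 20:
            raise ValueError("grid must be at least 20 x 20")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])

    def targets(self) -> np.ndarray:
        if self.clonality_targets is not None:
            return np.asarray(self.clonality_targets, float)
        return np.linspace(0.18, 0.93, self.n_sites)

    def site_names(self) -> list:
        return [f"site{i + 1:02d}" for i in range(self.n_sites)]


# ---------------------------------------------------------------------------
# genotypes


def _draw_site_freqs(ancestral: np.ndarray, F: float, rng) -> np.ndarray:
    if F == 0.0:
        return ancestral.copy()
    return rng.dirichlet(ancestral * (1.0 - F) / F)


def simulate_genotypes(
    config: SynthConfig, rng: np.random.Generator | None = None
) -> tuple[list[SampleRecord], dict]:
    """Clonal microsatellite panels per site plus a ground-truth record.

    The number of genets at a site is fixed by its target R via
    ``G = round(1 + R (N - 1))``, so realized richness equals the target
    exactly unless two genets collide on the same MLG (vanishingly rare at
    9 polymorphic loci; such draws are rejected and retried).
    """
    rng = rng or config.rng(1)
    n_alleles = (
        np.asarray(config.alleles_per_locus)
        if config.alleles_per_locus is not None
        else rng.integers(3, 17, size=config.n_loci)
    )
    ancestral = [rng.dirichlet(np.ones(k)) for k in n_alleles]
    allele_sizes = [100 + 2 * np.arange(k) for k in n_alleles]
    N = config.samples_per_site
    records: list[SampleRecord] = []
    truth = {
        "ancestral_freqs": ancestral,
        "allele_sizes": allele_sizes,
        "fst_target": config.fst_target,
        "sites": {},
    }
    for site, r_target in zip(config.site_names(), config.targets()):
        G = int(round(1 + r_target * (N - 1)))
        G = max(1, min(N, G))
        if G > N:
            raise ValueError(f"site {site}: clonality target needs G > N")
        site_freqs = [
            _draw_site_freqs(p, config.fst_target, rng) for p in ancestral
        ]
        genets = None
        for _ in range(20):
            drawn = []
            for _g in range(G):
                calls = []
                for f, sizes in zip(site_freqs, allele_sizes):
                    a, b = rng.choice(len(f), size=2, p=f)
                    calls.append((int(sizes[a]), int(sizes[b])))
                drawn.append(MultilocusGenotype(calls))
            if len({g.calls for g in drawn}) == G:
                genets = drawn
                break
        if genets is None:
            raise ValueError(
                f"site {site}: could not draw {G} distinct genets "
                "(loci not polymorphic enough for the clonality target)"
            )
        # geometric clone-size law: every genet keeps one ramet, extras are
        # multinomial with geometrically decaying weights (dominant clones)
        q = config.clone_dominance
        w = q * (1 - q) ** np.arange(G)
        extras = rng.multinomial(N - G, w / w.sum())
        sizes = 1 + extras
        genet_idx = np.repeat(np.arange(G), sizes)
        rng.shuffle(genet_idx)
        assignment = {}
        for i, gi in enumerate(genet_idx):
            quadrat = f"Q{i % 3 + 1}"
            sid = f"{site}_{quadrat}_{i + 1:02d}"
            records.append(SampleRecord(sid, site, quadrat, genets[gi]))
            assignment[sid] = int(gi)
        truth["sites"][site] = {
            "R_target": float(r_target),
            "G": G,
            "site_freqs": site_freqs,
            "genet_of_sample": assignment,
        }
    return records, truth


# ---------------------------------------------------------------------------
# bay


def simulate_bay(
    config: SynthConfig,
) -> tuple[CurrentField, list[HabitatPatch]]:
    """Enclosed-bay current field and shallow habitat patches.

    Velocities are central differences of a double-gyre streamfunction (so
    the discrete divergence vanishes identically) plus a uniform tidal
    oscillation over water. Bathymetry is a bowl, shallow at the shore;
    patches sit in shallow cells spaced around the bay with habitat areas
    spanning two orders of magnitude.
    """
    ny, nx = config.grid_shape
    L = config.domain_km * 1000.0
    x = (np.arange(nx) + 0.5) * L / nx
    y = (np.arange(ny) + 0.5) * L / ny
    X, Y = np.meshgrid(x, y)
    mask = np.zeros((ny, nx), bool)
    mask[2:-2, 2:-2] = True
    mouth = slice(nx // 2 - 2, nx // 2 + 2)
    mask[0:2, mouth] = True  # bay mouth on the southern edge
    rho = np.sqrt(((X - L / 2) / (L / 2)) ** 2 + ((Y - L / 2) / (L / 2)) ** 2)
    depth = np.where(mask, 2.0 + 18.0 * np.clip(1.0 - rho**2, 0.0, 1.0), 0.0)
    depth[mask] = np.maximum(depth[mask], 1.5)
    psi = (
        config.gyre_strength
        * np.sin(2 * np.pi * X / L)
        * np.sin(np.pi * Y / L)
    )
    # u = dpsi/dy, v = -dpsi/dx by central differences of the smooth
    # streamfunction: the discrete divergence vanishes identically, and
    # zeroing land cells afterwards keeps boundary gradients physical
    u0 = np.gradient(psi, y, axis=0)
    v0 = -np.gradient(psi, x, axis=1)
    u0[~mask] = 0.0
    v0[~mask] = 0.0
    nt = int(config.field_days * 24) + 1
    t = np.arange(nt, dtype=float)
    phase = 2 * np.pi * t / config.tidal_period_h
    u = u0[None] + config.tidal_amplitude * np.sin(phase)[:, None, None] * mask
    v = v0[None] + 0.3 * config.tidal_amplitude * np.cos(phase)[:, None, None] * mask
    if config.current_noise > 0:
        rng = config.rng(2)
        u = u + rng.normal(0, config.current_noise, u.shape) * mask
        v = v + rng.normal(0, config.current_noise, v.shape) * mask
    field = CurrentField(x=x, y=y, time=t, u=u, v=v, depth=depth, mask=mask)
    # shallow ring cells, spaced by bearing around the bay centre
    shallow = np.argwhere(mask & (depth < 7.0) & (depth > 0))
    if len(shallow) < config.n_patches:
        raise ValueError(
            f"{config.n_patches} patches requested but only {len(shallow)} shallow cells"
        )
    ang = np.arctan2(shallow[:, 0] - ny / 2, shallow[:, 1] - nx / 2)
    order = np.argsort(ang)
    pick = order[np.linspace(0, len(order) - 1, config.n_patches, dtype=int)]
    areas = np.logspace(3.0, 5.3, config.n_patches)
    patches = []
    for name, cell_i, area in zip(config.site_names(), pick, areas):
        iy, ix = shallow[cell_i]
        cells = {(int(iy), int(ix))}
        for dy_, dx_ in ((0, 1), (1, 0)):
            jy, jx = iy + dy_, ix + dx_
            if 0 <= jy < ny and 0 <= jx < nx and mask[jy, jx]:
                cells.add((int(jy), int(jx)))
        patches.append(
            HabitatPatch(
                id=name,
                cells=frozenset(cells),
                area=float(area),
                centroid=(float(x[ix]), float(y[iy])),
            )
        )
    return field, patches


# ---------------------------------------------------------------------------
# reproduction


def simulate_reproduction(
    inflow: Sequence[float] | pd.Series,
    config: SynthConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Seed/spathe densities and clonality targets tied to inflow.

    Log seed density is drawn lognormally; the site's genotypic richness is
    then a beta draw with logit mean linear in log seed density and log
    inflow (the generator's ground truth), and spathe density is seed
    density times lognormal noise, reproducing the strong seed-spathe
    correlation. Densities are strictly positive.
    """
    rng = rng or config.rng(3)
    inflow = pd.Series(inflow).astype(float)
    if (inflow <= 0).any():
        raise ValueError("inflow must be strictly positive to take logs")
    b0, b_seed, b_inflow = config.beta_truth
    log_seed = rng.normal(np.log(800.0), 1.5, size=len(inflow))
    eta = b0 + b_seed * log_seed + b_inflow * np.log(inflow.to_numpy())
    mu = 1.0 / (1.0 + np.exp(-eta))
    r = rng.beta(mu * config.phi, (1.0 - mu) * config.phi)
    r = np.clip(r, 0.02, 0.98)
    seed_density = np.exp(log_seed)
    spathe_density = seed_density * 0.5 * np.exp(
        rng.normal(0.0, config.spathe_noise_sd, size=len(inflow))
    )
    df = pd.DataFrame(
        {
            "site": list(inflow.index) if inflow.index.dtype == object else None,
            "seed_density": seed_density,
            "spathe_density": spathe_density,
            "inflow": inflow.to_numpy(),
            "R_target": r,
        }
    )
    if df["site"].isna().all():
        df["site"] = [f"site{i + 1:02d}" for i in range(len(df))]
    truth = {"beta": (b0, b_seed, b_inflow), "phi": config.phi, "mu": mu, "eta": eta}
    return df, truth
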