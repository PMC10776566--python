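"""Seeded synthetic inputs emulating the study's data structures.

Everything the pipeline consumes can be generated here: analytic ocean
velocity fields on a 0.08° grid (the resolution of the daily forcing the
dispersal model is built for), spawning-site geometries, Balding–Nichols
SNP genotypes with a controlled F_ST, haplotype alignments with a recorded
mutation graph, and telemetry tracks.

Randomness: one named generator per fixture kind, each derived from the
master seed via ``SeedSequence`` spawn keys, so adding one fixture never
shifts another.

Default design mirrors the study system: six localities (Gironde, Tejo,
Algarve, Guadalquivir, Banc d'Arguin, Senegal) with sample sizes
12/23/12/16/17/7 (n = 87) and 1,534 SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import SimpleNamespace

import networkx as nx
import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .dispersal import SpawningSite, VelocityField
from .geo import M_PER_DEG_LAT
from .popgen_mtdna import HaplotypeAlignment
from .popgen_snp import GenotypeDataset
from .telemetry import TelemetryTrack

__all__ = [
    "FixtureConfig",
    "make_velocity_field",
    "make_genotypes",
    "make_haplotypes",
    "make_track",
    "make_sites",
]

STUDY_LOCALITIES = ("Gironde", "Tejo", "Algarve", "Guadalquivir", "BancDArguin", "Senegal")
STUDY_SAMPLE_SIZES = (12, 23, 12, 16, 17, 7)

_RNG_STREAMS = {"velocity": 0, "genotypes": 1, "haplotypes": 2, "tracks": 3, "sites": 4}


@dataclass
class FixtureConfig:
    """Shared knobs for all fixture generators.

    ``grid_extent`` is (lon_min, lon_max, lat_min, lat_max) in degrees;
    ``grid_step`` defaults to 0.08° to mirror the forcing grid. ``fst_target``
    is the Balding–Nichols F (expected Weir–Cockerham θ of the generated
    genotypes).
    """

    seed: int = 0
    grid_extent: tuple = (-10.0, -6.0, 36.0, 40.0)
    grid_step: float = 0.08
    n_days: int = 30
    start_date: str = "2008-01-01"
    n_pops: int = 6
    n_loci: int = 1534
    n_ind_per_pop: tuple = STUDY_SAMPLE_SIZES
    pop_names: tuple = STUDY_LOCALITIES
    fst_target: float = 0.05
    ancestral_maf_range: tuple = (0.1, 0.5)
    missing_rate: float = 0.0
    reproducibility_range: tuple = (0.99, 1.0)

    def __post_init__(self):
        if self.grid_step <= 0:
            raise ValueError("grid_step must be > 0")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if not (0.0 <= self.fst_target < 1.0):
            raise ValueError("fst_target must lie in [0, 1)")
        if len(self.n_ind_per_pop) != self.n_pops or len(self.pop_names) != self.n_pops:
            raise ValueError("n_ind_per_pop and pop_names must have n_pops entries")
        lo, hi = self.ancestral_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("ancestral_maf_range must lie in (0, 0.5]")

    def rng(self, stream: str) -> np.random.Generator:
        """Named per-fixture-kind generator derived from the master seed."""
        key = _RNG_STREAMS[stream]
        return np.random.default_rng(np.random.SeedSequence(entropy=self.seed, spawn_key=(key,)))


# ---------------------------------------------------------------- velocity

def _grid(config: FixtureConfig):
    lon0, lon1, lat0, lat1 = config.grid_extent
    lon = np.arange(lon0, lon1 + config.grid_step / 2, config.grid_step)
    lat = np.arange(lat0, lat1 + config.grid_step / 2, config.grid_step)
    time = np.datetime64(config.start_date, "ns") + np.arange(config.n_days) * np.timedelta64(1, "D")
    return lon, lat, time


def double_gyre_velocity(lon, lat, t_days, extent, amplitude=0.1, eps=0.1, period_days=10.0):
    """Closed-form double-gyre velocities (m/s) at given coordinates.

    The stream function is ψ = A sin(π f(x,t)) sin(π y) on the unit-scaled
    domain x∈[0,2], y∈[0,1], with f = ε sin(ωt)x² + (1−2ε sin(ωt))x; the
    velocity is its curl, u = −∂ψ/∂y, v = ∂ψ/∂x.
    """
    lon0, lon1, lat0, lat1 = extent
    x = 2.0 * (np.asarray(lon) - lon0) / (lon1 - lon0)
    y = (np.asarray(lat) - lat0) / (lat1 - lat0)
    om = 2.0 * np.pi / period_days
    st = np.sin(om * t_days)
    a_t = eps * st
    b_t = 1.0 - 2.0 * eps * st
    f = a_t * x**2 + b_t * x
    dfdx = 2.0 * a_t * x + b_t
    u = -np.pi * amplitude * np.sin(np.pi * f) * np.cos(np.pi * y)
    v = np.pi * amplitude * np.cos(np.pi * f) * np.sin(np.pi * y) * dfdx
    return u, v


def make_velocity_field(config: FixtureConfig, kind: str, params: dict | None = None, land_polygons=None) -> VelocityField:
    """Generate an analytic or random-smooth velocity field on the fixture grid.

    Kinds: ``zero``, ``uniform`` (params u, v in m/s), ``double_gyre``
    (params amplitude, eps, period_days), ``random_smooth`` (params
    amplitude, n_modes), ``solid_rotation`` (params period_days, center).
    """
    params = dict(params or {})
    lon, lat, time = _grid(config)
    nt, ny, nx = time.size, lat.size, lon.size
    LON, LAT = np.meshgrid(lon, lat)
    u = np.zeros((nt, ny, nx))
    v = np.zeros((nt, ny, nx))

    if kind == "zero":
        pass
    elif kind == "uniform":
        if "u" not in params or "v" not in params:
            raise ValueError("uniform field requires params u and v (m/s)")
        u[:] = float(params["u"])
        v[:] = float(params["v"])
    elif kind == "double_gyre":
        amplitude = params.get("amplitude", 0.1)
        eps = params.get("eps", 0.1)
        period = params.get("period_days", 10.0)
        for k in range(nt):
            uu, vv = double_gyre_velocity(LON, LAT, float(k), config.grid_extent, amplitude, eps, period)
            u[k], v[k] = uu, vv
    elif kind == "random_smooth":
        amplitude = params.get("amplitude", 0.1)
        n_modes = int(params.get("n_modes", 3))
        rng = config.rng("velocity")
        lon0, lon1, lat0, lat1 = config.grid_extent
        x = (LON - lon0) / (lon1 - lon0)
        y = (LAT - lat0) / (lat1 - lat0)
        for k in range(nt):
            psi = np.zeros_like(x)
            for _ in range(n_modes):
                kx, ky = rng.integers(1, 4, size=2)
                phx, phy = rng.uniform(0, 2 * np.pi, size=2)
                amp = rng.normal(0, 1.0)
                psi += amp * np.sin(np.pi * kx * x + phx) * np.sin(np.pi * ky * y + phy)
            # velocities from the discrete curl of the stream function
            dy = (lat[1] - lat[0]) if ny > 1 else 1.0
            dx = (lon[1] - lon[0]) if nx > 1 else 1.0
            gy, gx = np.gradient(psi, dy, dx)
            scale = amplitude / max(np.max(np.hypot(gx, gy)), 1e-12)
            u[k] = -gy * scale
            v[k] = gx * scale
    elif kind == "solid_rotation":
        period = params.get("period_days", 10.0)
        lon_c = params.get("lon_c", 0.5 * (config.grid_extent[0] + config.grid_extent[1]))
        lat_c = params.get("lat_c", 0.5 * (config.grid_extent[2] + config.grid_extent[3]))
        omega = 2.0 * np.pi / (period * 86400.0)  # rad/s
        # planar rotation about the centre in local-metre coordinates
        xm = (LON - lon_c) * M_PER_DEG_LAT * np.cos(np.radians(LAT))
        ym = (LAT - lat_c) * M_PER_DEG_LAT
        u[:] = -omega * ym
        v[:] = omega * xm
    else:
        raise ValueError(f"unknown velocity field kind {kind!r}")

    mask = np.zeros((ny, nx), dtype=bool)
    polys = list(land_polygons or [])
    if polys:
        from shapely.prepared import prep
        from shapely.geometry import Point

        for poly in polys:
            pp = prep(poly)
            for i in range(ny):
                for j in range(nx):
                    if not mask[i, j] and pp.contains(Point(lon[j], lat[i])):
                        mask[i, j] = True
    return VelocityField(lon=lon, lat=lat, time=time, u=u, v=v, land_mask=mask, land_polygons=polys)


# ---------------------------------------------------------------- genotypes

def make_genotypes(config: FixtureConfig) -> GenotypeDataset:
    """Balding–Nichols genotypes with expected F_ST = ``fst_target``.

    Ancestral allele frequencies are uniform on ``ancestral_maf_range``;
    each subpopulation's frequency is Beta(p(1−F)/F, (1−p)(1−F)/F) (the
    ancestral frequency itself in the F→0 limit), and genotypes are two
    binomial allele copies. Missing calls are injected uniformly at random
    at ``missing_rate``; per-locus reproducibility metadata is drawn on
    ``reproducibility_range``.
    """
    rng = config.rng("genotypes")
    F = config.fst_target
    L = config.n_loci
    p_anc = rng.uniform(*config.ancestral_maf_range, size=L)
    pop_freqs = np.empty((config.n_pops, L))
    for k in range(config.n_pops):
        if F == 0.0:
            pop_freqs[k] = p_anc
        else:
            a = p_anc * (1.0 - F) / F
            b = (1.0 - p_anc) * (1.0 - F) / F
            pop_freqs[k] = rng.beta(a, b)
    dosages = []
    labels = []
    ids = []
    for k, (name, n_k) in enumerate(zip(config.pop_names, config.n_ind_per_pop)):
        dosages.append(rng.binomial(2, pop_freqs[k], size=(n_k, L)))
        labels.extend([name] * n_k)
        ids.extend([f"{name}_{i + 1:02d}" for i in range(n_k)])
    dosage = np.vstack(dosages).astype(np.int8)
    if config.missing_rate > 0:
        miss = rng.random(dosage.shape) < config.missing_rate
        dosage[miss] = -1
    meta = pd.DataFrame(
        {"reproducibility": rng.uniform(*config.reproducibility_range, size=L)},
        index=pd.Index([f"L{j + 1:05d}" for j in range(L)], name="locus"),
    )
    gd = GenotypeDataset(
        ind_ids=ids,
        localities=np.array(labels, dtype=object),
        locus_ids=list(meta.index),
        dosage=dosage,
        locus_meta=meta,
    )
    gd.true_pop_freqs = pop_freqs
    gd.true_ancestral_freqs = p_anc
    return gd


# ---------------------------------------------------------------- haplotypes

def make_haplotypes(
    config: FixtureConfig,
    n_haplotypes: int,
    seq_len: int,
    freq_by_pop: np.ndarray,
    topology: str = "random",
) -> HaplotypeAlignment:
    """Haplotype alignment with a recorded single-mutation genealogy.

    Haplotype 1 is the ancestral sequence; each further haplotype attaches
    to an existing one (``star``: always the ancestor; ``random``: a random
    existing haplotype) by one substitution at a previously unused site, so
    the true mutation graph — returned on the alignment's ``truth``
    attribute — is known exactly. ``freq_by_pop`` rows (one per locality)
    must each sum to 1; per-locality sample counts follow the config.
    """
    freq_by_pop = np.asarray(freq_by_pop, dtype=float)
    if freq_by_pop.shape != (config.n_pops, n_haplotypes):
        raise ValueError("freq_by_pop must be (n_pops, n_haplotypes)")
    if not np.allclose(freq_by_pop.sum(axis=1), 1.0):
        raise ValueError("rows of freq_by_pop must sum to 1")
    if seq_len < n_haplotypes - 1:
        raise ValueError("seq_len must be >= n_haplotypes - 1 to host the mutations")
    rng = config.rng("haplotypes")
    bases = np.array(list("ACGT"))
    anc = rng.choice(bases, size=seq_len)
    haps = [anc.copy()]
    graph = nx.Graph()
    graph.add_node("H1")
    free_sites = list(rng.permutation(seq_len))
    for h in range(1, n_haplotypes):
        parent = 0 if topology == "star" else int(rng.integers(0, h))
        site = free_sites.pop()
        seq = haps[parent].copy()
        current = seq[site]
        seq[site] = rng.choice([b for b in "ACGT" if b != current])
        haps.append(seq)
        graph.add_edge(f"H{parent + 1}", f"H{h + 1}", site=int(site))
    ids, locs, seqs = [], [], []
    for k, (name, n_k) in enumerate(zip(config.pop_names, config.n_ind_per_pop)):
        draws = rng.choice(n_haplotypes, size=n_k, p=freq_by_pop[k])
        for i, d in enumerate(draws):
            ids.append(f"{name}_mt{i + 1:02d}")
            locs.append(name)
            seqs.append("".join(haps[d]))
    aln = HaplotypeAlignment(ids=ids, localities=locs, sequences=seqs)
    aln.truth = SimpleNamespace(
        graph=graph,
        haplotypes={f"H{i + 1}": "".join(h) for i, h in enumerate(haps)},
    )
    return aln


# ---------------------------------------------------------------- tracks

def make_track(
    config: FixtureConfig,
    waypoints,
    times,
    fish_id: str = "fish01",
    noise_sd_km: float = 0.0,
    sources=None,
) -> TelemetryTrack:
    """Telemetry track through given waypoints, with optional position noise."""
    if len(waypoints) != len(times):
        raise ValueError("waypoints and times must have equal length")
    times = np.asarray(times, dtype="datetime64[ns]")
    if times.size > 1 and not np.all(np.diff(times) > np.timedelta64(0, "ns")):
        raise ValueError("times must be strictly increasing")
    lons = np.array([w[0] for w in waypoints], dtype=float)
    lats = np.array([w[1] for w in waypoints], dtype=float)
    if noise_sd_km > 0:
        rng = config.rng("tracks")
        deg = noise_sd_km / (M_PER_DEG_LAT / 1000.0)
        lats = lats + rng.normal(0, deg, size=lats.size)
        lons = lons + rng.normal(0, deg, size=lons.size) / np.cos(np.radians(lats))
    return TelemetryTrack(fish_id=fish_id, times=times, lons=lons, lats=lats, sources=sources)


# ---------------------------------------------------------------- sites

def make_sites(
    config: FixtureConfig,
    specs,
    field: VelocityField | None = None,
    cell_km: float = 3.0,
    settlement_buffer_km: float = 10.0,
) -> list:
    """Square spawning sites from (name, lon_c, lat_c, side_km, season) specs."""
    sites = []
    for name, lon_c, lat_c, side_km, season in specs:
        half_lat = side_km / 2.0 / (M_PER_DEG_LAT / 1000.0)
        half_lon = half_lat / np.cos(np.radians(lat_c))
        poly = Polygon(
            [
                (lon_c - half_lon, lat_c - half_lat),
                (lon_c + half_lon, lat_c - half_lat),
                (lon_c + half_lon, lat_c + half_lat),
                (lon_c - half_lon, lat_c + half_lat),
            ]
        )
        sites.append(
            SpawningSite.from_polygon(
                name, poly, season, field=field, cell_km=cell_km, settlement_buffer_km=settlement_buffer_km
            )
        )
    return sites
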