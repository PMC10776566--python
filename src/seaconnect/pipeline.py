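"""End-to-end orchestration: fixtures → dispersal → genetics → clustering → telemetry.

A single YAML config (strict schema: unknown keys are rejected) drives a
reproducible run. Every stage's RNG seed is derived deterministically from
the master seed, so identical config+seed gives checksum-identical
numerical outputs. Stage failures are recorded in the manifest and their
dependents skipped.
"""

from __future__ import annotations

import hashlib
import json
import time as _time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import clustering as cl
from . import dispersal as dsp
from . import fixtures as fx
from . import popgen_mtdna as mt
from . import popgen_snp as ps
from . import telemetry as tel

__all__ = ["RunConfig", "run_all", "load_config"]

SCHEMA_VERSION = 1
_STAGE_SEEDS = {"fixtures": 10, "dispersal": 11, "popgen_snp": 12, "popgen_mtdna": 13, "clustering": 14, "telemetry": 15}


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class FixtureBlock(_Strict):
    grid_extent: tuple[float, float, float, float] = (-10.0, -6.0, 36.0, 40.0)
    grid_step: float = 0.08
    n_days: int = 30
    start_date: str = "2008-01-01"
    n_pops: int = 6
    n_loci: int = 1534
    n_ind_per_pop: list[int] = Field(default_factory=lambda: list(fx.STUDY_SAMPLE_SIZES))
    pop_names: list[str] = Field(default_factory=lambda: list(fx.STUDY_LOCALITIES))
    fst_target: float = 0.05
    ancestral_maf_range: tuple[float, float] = (0.1, 0.5)
    missing_rate: float = 0.02


class SiteSpec(_Strict):
    name: str
    lon_c: float
    lat_c: float
    side_km: float = 9.0
    season: tuple[int, int] = (152, 196)


class DispersalBlock(_Strict):
    enabled: bool = True
    field_kind: str = "double_gyre"
    field_params: dict = Field(default_factory=dict)
    sites: list[SiteSpec] = Field(default_factory=list)
    years: list[int] = Field(default_factory=lambda: [2008])
    release_per_day: int = 1
    step_hours: float = 1.0
    max_days: int = 30
    cell_km: float = 3.0
    settlement_buffer_km: float = 10.0
    min_age_hours: float = 0.0


class PopgenSnpBlock(_Strict):
    enabled: bool = True
    min_call_rate: float = 0.95
    min_maf: float = 0.05
    min_reproducibility: float | None = None
    max_missing_per_ind: float = 0.5
    n_perm: int = 199
    coords: dict[str, tuple[float, float]] = Field(default_factory=dict)


class PopgenMtdnaBlock(_Strict):
    enabled: bool = True
    n_haplotypes: int = 6
    seq_len: int = 60
    n_perm: int = 199


class ClusteringBlock(_Strict):
    enabled: bool = True
    k_min: int = 1
    k_max: int = 3
    replicates: int = 3
    iters: int = 600
    burnin: int = 150
    n_loci_subset: int | None = 300


class TrackSpec(_Strict):
    id: str
    waypoints: list[tuple[float, float]]
    times: list[str]


class TelemetryBlock(_Strict):
    enabled: bool = True
    tracks: list[TrackSpec] = Field(default_factory=list)


class RunConfig(_Strict):
    """Validated, round-trippable run configuration."""

    schema_version: int = SCHEMA_VERSION
    seed: int = 0
    out_dir: str = "run_out"
    fixtures: FixtureBlock = Field(default_factory=FixtureBlock)
    dispersal: DispersalBlock = Field(default_factory=lambda: DispersalBlock(enabled=False))
    popgen_snp: PopgenSnpBlock = Field(default_factory=lambda: PopgenSnpBlock(enabled=False))
    popgen_mtdna: PopgenMtdnaBlock = Field(default_factory=lambda: PopgenMtdnaBlock(enabled=False))
    clustering: ClusteringBlock = Field(default_factory=lambda: ClusteringBlock(enabled=False))
    telemetry: TelemetryBlock = Field(default_factory=lambda: TelemetryBlock(enabled=False))

    def stage_seed(self, stage: str) -> int:
        ss = np.random.SeedSequence(entropy=self.seed, spawn_key=(_STAGE_SEEDS[stage],))
        return int(ss.generate_state(1)[0] % (2**31))


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)


def dump_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(json.loads(config.model_dump_json()), fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute all enabled stages in dependency order; return the manifest.

    The manifest records per-stage status, output paths with SHA-256
    checksums, timings, and the config echo; it is also written to
    ``manifest.json`` in the output directory.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "schema_version": config.schema_version,
        "seed": config.seed,
        "stages": {},
        "config": json.loads(config.model_dump_json()),
    }
    log_lines = []
    fcfg = config.fixtures
    fixture_config = fx.FixtureConfig(
        seed=config.stage_seed("fixtures"),
        grid_extent=tuple(fcfg.grid_extent),
        grid_step=fcfg.grid_step,
        n_days=fcfg.n_days,
        start_date=fcfg.start_date,
        n_pops=fcfg.n_pops,
        n_loci=fcfg.n_loci,
        n_ind_per_pop=tuple(fcfg.n_ind_per_pop),
        pop_names=tuple(fcfg.pop_names),
        fst_target=fcfg.fst_target,
        ancestral_maf_range=tuple(fcfg.ancestral_maf_range),
        missing_rate=fcfg.missing_rate,
    )
    state: dict = {}

    def run_stage(name, enabled, func, depends=()):
        entry = {"status": "skipped", "outputs": {}, "elapsed_s": None}
        manifest["stages"][name] = entry
        if not enabled:
            log_lines.append(f"{name}: disabled")
            return
        for dep in depends:
            if manifest["stages"].get(dep, {}).get("status") != "complete":
                entry["status"] = "skipped_dependency"
                log_lines.append(f"{name}: skipped ({dep} incomplete)")
                return
        t0 = _time.perf_counter()
        try:
            paths = func()
            entry["outputs"] = {str(p.relative_to(out)): _sha256(p) for p in paths}
            entry["status"] = "complete"
        except Exception as exc:  # recorded, downstream skipped
            entry["status"] = "failed"
            entry["error"] = f"{type(exc).__name__}: {exc}"
        entry["elapsed_s"] = round(_time.perf_counter() - t0, 3)
        log_lines.append(f"{name}: {entry['status']} in {entry['elapsed_s']}s")

    # ---- fixtures ----
    def stage_fixtures():
        paths = []
        gd = fx.make_genotypes(fixture_config)
        state["genotypes"] = gd
        p = out / "genotypes.tsv"
        gd.to_tsv(p)
        paths.append(p)
        p = out / "genotypes.vcf"
        gd.to_vcf(p)
        paths.append(p)
        n_h = config.popgen_mtdna.n_haplotypes
        rng = fixture_config.rng("sites")  # separate stream from make_haplotypes' own
        freq = rng.dirichlet(np.ones(n_h) * 2.0, size=fixture_config.n_pops)
        aln = fx.make_haplotypes(fixture_config, n_h, config.popgen_mtdna.seq_len, freq)
        state["alignment"] = aln
        p = out / "mtdna.fasta"
        aln.to_fasta(p)
        paths.append(p)
        if config.dispersal.enabled:
            field = fx.make_velocity_field(fixture_config, config.dispersal.field_kind, config.dispersal.field_params)
            state["field"] = field
            p = out / "field.nc"
            field.to_netcdf(p)
            paths.append(p)
        if config.telemetry.tracks:
            tracks = [
                fx.make_track(fixture_config, t.waypoints, np.array(t.times, dtype="datetime64[ns]"), fish_id=t.id)
                for t in config.telemetry.tracks
            ]
            state["tracks"] = tracks
            p = out / "tracks.csv"
            tel.write_tracks_csv(tracks, p)
            paths.append(p)
        return paths

    run_stage("fixtures", True, stage_fixtures)

    # ---- dispersal ----
    def stage_dispersal():
        field = state["field"]
        dcfg = config.dispersal
        sites = fx.make_sites(
            fixture_config,
            [(s.name, s.lon_c, s.lat_c, s.side_km, tuple(s.season)) for s in dcfg.sites],
            field=field,
            cell_km=dcfg.cell_km,
            settlement_buffer_km=dcfg.settlement_buffer_km,
        )
        trajs = dsp.run_simulation(
            field,
            sites,
            years=dcfg.years,
            release_per_day=dcfg.release_per_day,
            step=dcfg.step_hours,
            max_days=dcfg.max_days,
            min_age_hours=dcfg.min_age_hours,
        )
        paths = []
        p = out / "trajectories.csv"
        trajs.to_dataframe().to_csv(p, index=False)
        paths.append(p)
        cm = dsp.connectivity_matrix(trajs, sites)
        p = out / "connectivity.csv"
        cm.to_dataframe().to_csv(p)
        paths.append(p)
        stats = dsp.dispersal_stats(trajs)
        p = out / "dispersal_stats.json"
        p.write_text(json.dumps(stats, indent=2, sort_keys=True))
        paths.append(p)
        return paths

    run_stage("dispersal", config.dispersal.enabled, stage_dispersal, depends=("fixtures",))

    # ---- nuclear SNPs ----
    def stage_popgen_snp():
        gcfg = config.popgen_snp
        gd = state["genotypes"]
        gd, sizes = ps.exclude_failed_samples(gd, gcfg.max_missing_per_ind)
        gd, counts = ps.filter_loci(gd, gcfg.min_call_rate, gcfg.min_maf, gcfg.min_reproducibility)
        state["genotypes_filtered"] = gd
        seed = config.stage_seed("popgen_snp")
        paths = []
        p = out / "qc_counts.json"
        p.write_text(json.dumps({"per_locality_n": {k: int(v) for k, v in sizes.items()}, "locus_filters": counts}, indent=2, sort_keys=True))
        paths.append(p)
        div = ps.diversity(gd)
        p = out / "diversity.csv"
        div.to_csv(p)
        paths.append(p)
        fst = ps.fst_pairwise_matrix(gd, n_perm=gcfg.n_perm, seed=seed)
        state["fst_snp"] = fst
        p = out / "fst_pairwise.csv"
        fst.to_dataframe().to_csv(p)
        paths.append(p)
        pv = pd.DataFrame(fst.pvalues, index=fst.labels, columns=fst.labels)
        p = out / "fst_pairwise_pvalues.csv"
        pv.to_csv(p)
        paths.append(p)
        if gcfg.coords:
            coords = pd.DataFrame(
                [(k, v[0], v[1]) for k, v in gcfg.coords.items()], columns=["locality", "lon", "lat"]
            ).set_index("locality")
            coords.index.name = "locality"
            coords = coords.loc[fst.labels]
            geo = ps.geographic_distance_matrix(coords.reset_index())
            r, pval = ps.ibd_mantel(fst, geo, n_perm=max(gcfg.n_perm, 99), seed=seed + 1)
            # transect positions: cumulative along-coast distance, north to south
            pos = {}
            acc = 0.0
            labs = list(coords.index)
            pos[labs[0]] = 0.0
            for i in range(1, len(labs)):
                acc += float(geo.values[i - 1, i])
                pos[labs[i]] = acc
            transect = ps.standardised_fst_transect(gd, fst, pos)
            p = out / "fst_transect.csv"
            transect.to_csv(p, index=False)
            paths.append(p)
            p = out / "ibd_mantel.json"
            p.write_text(json.dumps({"r": r, "p": pval, "n_perm": max(gcfg.n_perm, 99)}, indent=2))
            paths.append(p)
        scan = ps.outlier_scan(gd, n_perm=gcfg.n_perm, seed=seed + 2)
        p = out / "outliers.csv"
        scan.to_csv(p)
        paths.append(p)
        return paths

    run_stage("popgen_snp", config.popgen_snp.enabled, stage_popgen_snp, depends=("fixtures",))

    # ---- mtDNA ----
    def stage_popgen_mtdna():
        mcfg = config.popgen_mtdna
        aln = state["alignment"]
        table = mt.collapse_haplotypes(aln)
        seed = config.stage_seed("popgen_mtdna")
        paths = []
        p = out / "haplotype_table.csv"
        table.counts.to_csv(p)
        paths.append(p)
        freqs = table.counts / table.counts.sum(axis=0)
        p = out / "haplotype_frequencies.csv"
        freqs.to_csv(p)
        paths.append(p)
        div = {loc: mt.haplotype_diversity(table, loc) for loc in table.counts.columns}
        div["pooled"] = mt.haplotype_diversity(table)
        p = out / "haplotype_diversity.json"
        p.write_text(json.dumps(div, indent=2, sort_keys=True))
        paths.append(p)
        fst = mt.fst_haplotype_matrix(table, n_perm=mcfg.n_perm, seed=seed)
        p = out / "fst_mtdna.csv"
        fst.to_dataframe().to_csv(p)
        paths.append(p)
        net = mt.median_joining(table)
        p = out / "haplonet_edges.csv"
        mt.network_to_edgelist(net).to_csv(p, index=False)
        paths.append(p)
        import networkx as nx

        p = out / "haplonet.graphml"
        nx.write_graphml(net, p)
        paths.append(p)
        return paths

    run_stage("popgen_mtdna", config.popgen_mtdna.enabled, stage_popgen_mtdna, depends=("fixtures",))

    # ---- clustering ----
    def stage_clustering():
        ccfg = config.clustering
        gd = state.get("genotypes_filtered", state["genotypes"])
        if ccfg.n_loci_subset and gd.n_loci > ccfg.n_loci_subset:
            mask = np.zeros(gd.n_loci, bool)
            mask[: ccfg.n_loci_subset] = True
            gd = gd.subset(locus_mask=mask)
        base = config.stage_seed("clustering")
        runs = {}
        best_fit = {}
        for K in range(ccfg.k_min, ccfg.k_max + 1):
            lls = []
            for rep in range(ccfg.replicates):
                fit = cl.admixture_fit(gd, K, iters=ccfg.iters, burnin=ccfg.burnin, seed=base + 1000 * K + rep)
                lls.append(fit.mean_loglik)
                if K not in best_fit or fit.mean_loglik > best_fit[K].mean_loglik:
                    best_fit[K] = fit
            runs[K] = lls
        paths = []
        sel = cl.delta_k(runs) if ccfg.k_max - ccfg.k_min >= 2 else pd.DataFrame(
            {"K": list(runs), "mean_loglik": [float(np.mean(v)) for v in runs.values()]}
        ).set_index("K")
        p = out / "delta_k.csv"
        sel.to_csv(p)
        paths.append(p)
        k_show = sel.attrs.get("best_k") or max(2, ccfg.k_min)
        k_show = min(max(k_show, ccfg.k_min), ccfg.k_max)
        q = best_fit[k_show].q_dataframe(gd.ind_ids, gd.localities)
        p = out / "q_matrix.csv"
        q.to_csv(p, index=False)
        paths.append(p)
        dist = cl.allele_sharing_distance(gd)
        coords, eig = cl.pcoa(dist, n_axes=2)
        p = out / "pcoa.csv"
        pd.DataFrame({"individual": gd.ind_ids, "locality": gd.localities, "PC1": coords[:, 0], "PC2": coords[:, 1]}).to_csv(p, index=False)
        paths.append(p)
        if len(set(gd.localities)) >= 2:
            d = cl.dapc(gd)
            p = out / "dapc.csv"
            df = pd.DataFrame(d["scores"], columns=[f"LD{i + 1}" for i in range(d["scores"].shape[1])])
            df.insert(0, "individual", gd.ind_ids)
            df.insert(1, "locality", gd.localities)
            df["assignment"] = d["assignments"]
            df.to_csv(p, index=False)
            paths.append(p)
        return paths

    run_stage("clustering", config.clustering.enabled, stage_clustering, depends=("fixtures", "popgen_snp"))

    # ---- telemetry ----
    def stage_telemetry():
        tracks = state.get("tracks", [])
        summary = tel.summarise_tracks(tracks)
        p = out / "telemetry_summary.csv"
        summary.to_csv(p)
        return [p]

    run_stage("telemetry", config.telemetry.enabled and bool(config.telemetry.tracks), stage_telemetry, depends=("fixtures",))

    manifest["log"] = log_lines
    manifest["timestamp"] = pd.Timestamp.now().isoformat()
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
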