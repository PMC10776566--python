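# Bundled end-to-end toy configuration: all five analysis stages on small
# synthetic inputs. Runs in a couple of minutes on one CPU.
schema_version: 1
seed: 7
out_dir: scratch/toy_run

fixtures:
  grid_extent: [-10.0, -6.0, 36.0, 40.0]
  grid_step: 0.08
  n_days: 20
  start_date: "2008-01-01"
  n_pops: 6
  n_loci: 300
  n_ind_per_pop: [12, 23, 12, 16, 17, 7]
  pop_names: [Gironde, Tejo, Algarve, Guadalquivir, BancDArguin, Senegal]
  fst_target: 0.05
  ancestral_maf_range: [0.1, 0.5]
  missing_rate: 0.02

dispersal:
  enabled: true
  field_kind: double_gyre
  field_params: {amplitude: 0.25, eps: 0.15, period_days: 8.0}
  sites:
    - {name: NorthBank, lon_c: -8.6, lat_c: 38.8, side_km: 9.0, season: [3, 8]}
    - {name: SouthBank, lon_c: -7.6, lat_c: 37.2, side_km: 9.0, season: [3, 8]}
  years: [2008]
  release_per_day: 1
  step_hours: 1.0
  max_days: 8
  settlement_buffer_km: 10.0
  min_age_hours: 24.0

popgen_snp:
  enabled: true
  min_call_rate: 0.95
  min_maf: 0.05
  max_missing_per_ind: 0.5
  n_perm: 99
  coords:
    Gironde: [-1.1, 45.6]
    Tejo: [-9.0, 38.7]
    Algarve: [-7.9, 37.0]
    Guadalquivir: [-6.3, 36.8]
    BancDArguin: [-16.5, 20.0]
    Senegal: [-16.8, 14.7]

popgen_mtdna:
  enabled: true
  n_haplotypes: 6
  seq_len: 60
  n_perm: 99

clustering:
  enabled: true
  k_min: 1
  k_max: 3
  replicates: 3
  iters: 300
  burnin: 75
  n_loci_subset: 150

telemetry:
  enabled: true
  tracks:
    - id: meagre01
      waypoints: [[-7.9, 37.0], [-8.9, 37.0], [-9.3, 38.4], [-9.0, 38.7], [-8.9, 37.0], [-7.9, 37.0]]
      times: ["2019-01-05", "2019-03-01", "2019-05-10", "2019-06-20", "2019-09-01", "2019-11-15"]
    - id: meagre02
      waypoints: [[-7.5, 37.1], [-7.2, 37.1], [-7.5, 37.1]]
      times: ["2019-02-01", "2019-04-01", "2019-06-01"]
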