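# Demo experiment: three nanobody-GFP-like conditions measured in
# quadruplicate against a ligand-stabilized 20 bp reference, plus one row
# sweeping the same protein across four references of increasing strength.
# Protein characteristic forces are illustrative inputs, not measurements.
seed: 20141229

ramp:
  retraction_speed: 1.0        # um/s
  effective_stiffness: 100.0   # pN/nm -> loading rate 1e5 pN/s
  kT: 4.11                     # pN*nm

bond_width_nm: 1.0

references:
  shear40:
    length_bp: 40
    geometry: shear
  shear40_propynyl:
    length_bp: 40
    geometry: shear
    propynyl_count: 22         # 13 cytidines + 9 thymines substituted
  shear20_P1:
    length_bp: 20
    geometry: shear
    ligand: P1
  shear20_P2:
    length_bp: 20
    geometry: shear
    ligand: P2
  shear20_P3:
    length_bp: 20
    geometry: shear
    ligand: P3

conditions:
  nanobody_gfp_a:              # weaker binder, replicated row
    protein_force: 75.1
    reference: shear20_P1
    coupling_efficiency: 0.8
  nanobody_gfp_b:              # near-identical twin of condition a
    protein_force: 75.2
    reference: shear20_P1
    coupling_efficiency: 0.8
  nanobody_gfp_c:              # distinctly stronger binder
    protein_force: 77.0
    reference: shear20_P1
    coupling_efficiency: 0.8
  sweep_shear40:
    protein_force: 77.0
    reference: shear40
    coupling_efficiency: 0.8
  sweep_propynyl:
    protein_force: 77.0
    reference: shear40_propynyl
    coupling_efficiency: 0.8
  sweep_P3:
    protein_force: 77.0
    reference: shear20_P3
    coupling_efficiency: 0.8
  sweep_P2:
    protein_force: 77.0
    reference: shear20_P2
    coupling_efficiency: 0.8

layout:
  - [nanobody_gfp_a, nanobody_gfp_a, nanobody_gfp_a, nanobody_gfp_a]
  - [nanobody_gfp_b, nanobody_gfp_b, nanobody_gfp_b, nanobody_gfp_b]
  - [nanobody_gfp_c, nanobody_gfp_c, nanobody_gfp_c, nanobody_gfp_c]
  - [sweep_shear40, sweep_propynyl, sweep_P3, sweep_P2]

optical:
  gain_red: 50.0
  gain_fret: 40.0
  fret_factor: 0.6
  illumination:
    sigma: [120.0, 120.0]      # gentle Gaussian falloff across the field
    amplitude: 1.0

noise:
  background_offset: 100.0
  read_noise_sd: 5.0
  shot_noise: true

image:
  shape: [128, 128]
  probe_density: 50.0

analysis:
  min_start_snr: 5.0
  read_noise_sd: 5.0
  max_fret_ratio: 0.995
  ce_floor: 0.05
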