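# Base-case flow, metabolism and mechanics parameters for the idealized
# liver lobule.  Values regenerable from lobulesim.properties first-principles
# estimators (see lobulesim.properties.base_case_parameters).
#
# version: 1
name: table1_base_case
geometry:
  sinusoid_radius_um: 3.0        # half the 6 um sinusoid channel width
  tissue_edge_um: 24.0           # hepatocyte + ECM cube edge
  fiber_diameter_nm: 50.0        # collagen fiber diameter
  fiber_length_nm: 300.0         # collagen fiber length
flow:
  sinusoid_porosity: 0.7854      # pi/4, inscribed circular tube
  sinusoid_permeability_um2: 1.125   # R^2/8 with R = 3 um (1.140 Darcy)
  tissue_porosity: 0.2           # space-of-Disse ECM porosity (configurable)
  tissue_permeability_um2: 1.736e-7  # Carman-Kozeny, phi=0.2, d=50 nm
  blood_viscosity_pa_s: 3.5e-3
diffusion:
  sinusoid_diffusion_m2_s: 4.2e-10   # free (Stokes-Einstein) diffusion
  tissue_diffusion_m2_s: 4.2e-11     # restricted, 10x below free
kinetics:                        # paclitaxel hepatic elimination
  v_max_uM_min: 0.06
  K_m_uM: 10.0
mechanics:
  youngs_modulus_pa: 5.0e+3
  poissons_ratio: 0.35
  biot_alpha: 1.0
  skempton: 1.0
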