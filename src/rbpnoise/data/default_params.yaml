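# Fitted parameter set of the characterized MS2CP translation-factor circuit.
# Flat key-value file; keys are the dataclass field names of rbpnoise.params.

# --- Dose-response (Hill-Langmuir) constants ---
alpha_x: 1890.0     # AU, maximal regulator (eBFP2-MS2CP) expression
rho_x: 0.225        # dimensionless, transcriptional repression fold by LacI
theta_i: 116.0      # uM, LacI-IPTG effective dissociation constant
n_i: 2.38           # dimensionless, LacI cooperativity
alpha_y: 29000.0    # AU, maximal target (sfGFP) expression
rho_y: 0.016        # dimensionless, translational repression fold by MS2CP
theta_x: 610.0      # AU, regulator-RNA-motif effective dissociation constant
n_x: 5.0            # dimensionless, MS2CP cooperativity

# --- Growth and growth-coupling constants ---
mu0: 1.2            # 1/h, maximal growth rate (no TC)
theta_c: 526.0      # ng/mL, TC half-inhibition of growth
eps1_x: 0.196       # 1/h, regulator translation-scaling constant
eps2_x: 0.299       # 1/h, regulator translation-scaling constant
eps1_y: 0.246       # 1/h, target translation-scaling constant
eps2_y: 0.349       # 1/h, target translation-scaling constant
delta: 0.85         # h, cell-volume correction exponent for theta_x

# --- Noise constants (three-component decomposition) ---
eta2_x: 0.246       # dimensionless, regulator extrinsic-noise CV2
beta_x: 45.6        # AU, regulator intrinsic-noise Fano factor
eta2_lac: 6470.0    # uM^2, LacI expression-noise constant
eta2_y: 0.127       # dimensionless, target extrinsic-noise CV2
beta_y: 61.9        # AU, target intrinsic-noise Fano factor
gamma_y: 0.0233     # dimensionless, fluorescence-to-molecule conversion
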