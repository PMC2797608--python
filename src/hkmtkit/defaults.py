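"""Single source of the analysis defaults.

Every cutoff used by the analysis modules lives here so that a pipeline
run can be reproduced from one flat config. Values marked "published
protocol" mirror the superposition/coloring protocol the deposited
structures were analyzed with; the rest are geometric conventions of the
package (documented in docs/methods.md).
"""

# --- superposition (published protocol) ---
SEED_LEN = 15          # residues per seed alignment window
MAX_ITER = 10          # iteration cap of the weighted-superposition loop
WEIGHT_MODE = "inverted"   # 'printed' reproduces the published formula verbatim
WEIGHT_TOL = 1e-4      # early stop when max |dWi| falls below this

# --- sequence pairing ---
GAP_OPEN = -11.0
GAP_EXTEND = -1.0
SUBSTITUTION_MATRIX = "BLOSUM62"

# --- interactions ---
HB_MAX_DA = 3.5        # heavy-atom donor--acceptor cutoff, Angstrom
HB_MIN_ANGLE = 120.0   # antecedent-donor-acceptor minimum, degrees
CONTACT_CUTOFF = 4.0   # contact-shell cutoff, Angstrom
POLAR_CUTOFF = 3.5     # salt-bridge / polar-pair cutoff, Angstrom
PEPTIDE_MAX_RES = 25   # auto-detected peptide chain must be shorter than this

# --- specificity ---
CHANNEL_RADIUS = 6.0   # lysine-channel lining radius around the epsilon-N, Angstrom
HB_CUT = 3.5           # Tyr OH ... epsilon-N restraint distance, Angstrom
OH_BOND_LENGTH = 1.38  # idealized CZ-OH bond used for Phe->Tyr switches, Angstrom

# --- electrostatics ---
COULOMB_CONSTANT = 332.0637  # kcal*Angstrom/(mol*e^2)
DIELECTRIC = 80.0
KAPPA = 0.0            # inverse screening length, 1/Angstrom
CLAMP = 5.0            # display saturation, kcal/(mol*e) (published protocol)
PROBE_RADIUS = 1.4     # solvent probe, Angstrom
DOT_DENSITY = 1.0      # surface dots per Angstrom^2
PATCH_CUT = 5.0        # groove patch radius around the peptide, Angstrom
MIN_CHARGE_DIST = 0.1  # points closer than this to a charge site are skipped

# van der Waals radii by element, Angstrom
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "SE": 1.90, "ZN": 1.39, "FE": 1.40, "MG": 1.73,
}
VDW_DEFAULT = 1.70
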