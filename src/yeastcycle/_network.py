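"""Reaction network of the budding-yeast cell cycle oscillator.

This module is the single source of truth for the model structure: the 33
dynamic species, the reaction list with kinetic rate expressions, the
conservation pools, and the canonical parameter ordering.  Rate expressions
are plain arithmetic strings over species names, parameter names and the
three input signals (``FUS3``: pheromone MAPK active, ``HOG1``: osmostress
MAPK active, ``NU``: nutrition factor).  They are compiled once into a fast
numpy right-hand side and re-used verbatim for SBML serialisation, so the
simulated model and the exported model cannot drift apart.

Conventions
-----------
* abundances are particle numbers (molecules per cell), time is minutes;
* ``X_p`` denotes a Cdc28/Clb-site phosphoform, ``X_Hp`` the Hog1
  phosphoform of Sic1 (Thr173);
* cyclin species stand for their Cdc28 complexes (Cln2 = Cdc28-Cln1/2,
  Clb5 = Cdc28-Clb5/6, Clb3 = Cdc28-Clb3/4, Clb2 = Cdc28-Clb1/2);
* covalent-modification cycles use Michaelis-Menten kinetics (zero-order
  ultrasensitivity drives the switch-like transitions), binding steps use
  mass action;
* every protein-production rate constant (the ``ks_*`` set) is multiplied
  by the nutrition factor ``NU``.
"""

from __future__ import annotations

# --- species -----------------------------------------------------------------
# (name, role, pool) -- pool is the conservation pool the species belongs to,
# or None for species with turnover.  Complex species list constituents.

SPECIES_TABLE = [
    # name,            role,                  pools,                constituents
    ("Cln3",           "cyclin",              (),                   ()),
    ("Cln2",           "cyclin",              (),                   ()),
    ("Clb5",           "cyclin",              (),                   ()),
    ("Clb3",           "cyclin",              (),                   ()),
    ("Clb2",           "cyclin",              (),                   ()),
    ("Clb2_p",         "modified-form",       (),                   ()),
    ("Sic1",           "CKI",                 (),                   ()),
    ("Sic1_p",         "modified-form",       (),                   ()),
    ("Sic1_Hp",        "modified-form",       (),                   ()),
    ("Clb5_Sic1",      "complex",             (),                   ("Clb5", "Sic1")),
    ("Clb5_Sic1_Hp",   "complex",             (),                   ("Clb5", "Sic1_Hp")),
    ("Clb3_Sic1",      "complex",             (),                   ("Clb3", "Sic1")),
    ("Clb2_Sic1",      "complex",             (),                   ("Clb2", "Sic1")),
    ("Whi5",           "transcription-factor", ("Whi5",),           ()),
    ("Whi5_p",         "modified-form",       ("Whi5",),            ()),
    ("SBF",            "transcription-factor", ("SBF",),            ()),
    ("SBF_Whi5",       "complex",             ("SBF", "Whi5"),      ("SBF", "Whi5")),
    ("SBF_p",          "modified-form",       ("SBF",),             ()),
    ("MBF",            "transcription-factor", ("MBF",),            ()),
    ("MBF_a",          "transcription-factor", ("MBF",),            ()),
    ("Mcm1_a",         "transcription-factor", (),                  ()),
    ("APC_a",          "complex",             (),                   ()),
    ("Cdc14",          "phosphatase",         ("Cdc14",),           ()),
    ("Cdc14_p",        "phosphatase",         ("Cdc14",),           ()),
    ("Net1",           "kinase",              ("Net1",),            ()),
    ("Net1_p",         "modified-form",       ("Net1",),            ()),
    ("Swi5_a",         "transcription-factor", (),                  ()),
    ("Swe1",           "kinase",              (),                   ()),
    ("Swe1_p",         "modified-form",       (),                   ()),
    ("Far1",           "CKI",                 (),                   ()),
    ("Far1_p",         "modified-form",       (),                   ()),
    ("Cln2_Far1_p",    "complex",             (),                   ("Cln2", "Far1_p")),
    ("Cln3_Far1_p",    "complex",             (),                   ("Cln3", "Far1_p")),
]

SPECIES = [row[0] for row in SPECIES_TABLE]
SPECIES_INDEX = {name: i for i, name in enumerate(SPECIES)}

N_SPECIES = len(SPECIES)

# conservation pools: neither produced nor degraded, only converted
POOLS = {
    "SBF": ("SBF", "SBF_Whi5", "SBF_p"),
    "Whi5": ("Whi5", "Whi5_p", "SBF_Whi5"),
    "MBF": ("MBF", "MBF_a"),
    "Cdc14": ("Cdc14", "Cdc14_p"),
    "Net1": ("Net1", "Net1_p"),
}

# --- reactions ---------------------------------------------------------------
# (name, stoichiometry, rate expression)

REACTIONS = [
    # protein production (all scaled by the nutrition factor NU)
    ("syn_cln3", {"Cln3": 1}, "NU * ks_cln3"),
    ("syn_cln2", {"Cln2": 1}, "NU * ks_cln2 * SBF / (1 + HOG1 * kh_cln2)"),
    ("syn_clb5", {"Clb5": 1}, "NU * ks_clb5 * MBF_a / (1 + HOG1 * kh_clb5)"),
    ("syn_clb3", {"Clb3": 1}, "NU * ks_clb3 * Clb5"),
    ("syn_clb2", {"Clb2": 1}, "NU * ks_clb2 * Mcm1_a"),
    ("syn_sic1", {"Sic1": 1}, "NU * (ks_sic1 + ks_sic1_swi5 * Swi5_a)"),
    ("syn_swe1", {"Swe1": 1}, "NU * ks_swe1"),
    ("syn_far1", {"Far1": 1}, "NU * (ks_far1 + FUS3 * ks_far1_fus3)"),
    # degradation
    ("deg_cln3", {"Cln3": -1}, "kd_cln3 * Cln3"),
    ("deg_cln2", {"Cln2": -1}, "kd_cln2 * Cln2"),
    ("deg_clb5", {"Clb5": -1}, "(kd_clb5 + kd_clb5_apc * APC_a) * Clb5"),
    ("deg_clb3", {"Clb3": -1}, "(kd_clb3 + kd_clb3_apc * APC_a) * Clb3"),
    ("deg_clb2", {"Clb2": -1}, "(kd_clb2 + kd_clb2_apc * APC_a) * Clb2"),
    ("deg_clb2_p", {"Clb2_p": -1}, "(kd_clb2 + kd_clb2_apc * APC_a) * Clb2_p"),
    ("deg_sic1", {"Sic1": -1}, "kd_sic1 * Sic1"),
    ("deg_sic1_p", {"Sic1_p": -1}, "kd_sic1p * Sic1_p"),
    # the Hog1 phosphoform is exempt from CDK-triggered turnover
    ("deg_sic1_hp", {"Sic1_Hp": -1}, "kd_sic1 * Sic1_Hp"),
    ("deg_swe1", {"Swe1": -1}, "kd_swe1 * Swe1"),
    ("deg_swe1_p", {"Swe1_p": -1}, "kd_swe1p * Swe1_p"),
    ("deg_far1", {"Far1": -1}, "(kd_far1 + kd_far1_cln2 * Cln2) * Far1"),
    ("deg_far1_p", {"Far1_p": -1}, "(kd_far1p + kd_far1_cln2 * Cln2) * Far1_p"),
    # degradation of the cyclin moiety inside CKI complexes (APC-driven)
    ("deg_clb5_sic1_cyc", {"Clb5_Sic1": -1, "Sic1": 1},
     "(kd_clb5 + kd_clb5_apc * APC_a) * Clb5_Sic1"),
    ("deg_clb5_sic1_hp_cyc", {"Clb5_Sic1_Hp": -1, "Sic1_Hp": 1},
     "(kd_clb5 + kd_clb5_apc * APC_a) * Clb5_Sic1_Hp"),
    ("deg_clb3_sic1_cyc", {"Clb3_Sic1": -1, "Sic1": 1},
     "(kd_clb3 + kd_clb3_apc * APC_a) * Clb3_Sic1"),
    ("deg_clb2_sic1_cyc", {"Clb2_Sic1": -1, "Sic1": 1},
     "(kd_clb2 + kd_clb2_apc * APC_a) * Clb2_Sic1"),
    # CDK-triggered destruction of complexed Sic1 (releases the cyclin);
    # Clb5_Sic1_Hp is exempt (Hog1-stabilised Sic1)
    ("deg_clb5_sic1_cki", {"Clb5_Sic1": -1, "Clb5": 1},
     "(kp_sic1c_cln2 * Cln2 + kp_sic1c_clb5 * Clb5) * Clb5_Sic1"),
    ("deg_clb3_sic1_cki", {"Clb3_Sic1": -1, "Clb3": 1},
     "(kp_sic1c_cln2 * Cln2 + kp_sic1c_clb5 * Clb5) * Clb3_Sic1"),
    ("deg_clb2_sic1_cki", {"Clb2_Sic1": -1, "Clb2": 1},
     "(kp_sic1c_cln2 * Cln2 + kp_sic1c_clb5 * Clb5) * Clb2_Sic1"),
    # Far1 complexes: degradation of either moiety dissolves the complex
    ("deg_cln2_far1_cyc", {"Cln2_Far1_p": -1, "Far1_p": 1},
     "kd_cln2 * Cln2_Far1_p"),
    ("deg_cln3_far1_cyc", {"Cln3_Far1_p": -1, "Far1_p": 1},
     "kd_cln3 * Cln3_Far1_p"),
    ("deg_cln2_far1_cki", {"Cln2_Far1_p": -1, "Cln2": 1},
     "(kd_far1p + kd_far1_cln2 * Cln2) * Cln2_Far1_p"),
    ("deg_cln3_far1_cki", {"Cln3_Far1_p": -1, "Cln3": 1},
     "(kd_far1p + kd_far1_cln2 * Cln2) * Cln3_Far1_p"),
    # Whi5 phosphorylation by Cln3 and Cln1/2 kinase (nuclear exclusion)
    ("pho_whi5", {"Whi5": -1, "Whi5_p": 1},
     "(kp_whi5_cln3 * Cln3 + kp_whi5_cln2 * Cln2) * Whi5 / (Km_whi5 + Whi5)"),
    ("pho_sbf_whi5", {"SBF_Whi5": -1, "SBF": 1, "Whi5_p": 1},
     "(kp_sbfwhi5_cln3 * Cln3 + kp_sbfwhi5_cln2 * Cln2) * SBF_Whi5"
     " / (Km_sbfwhi5 + SBF_Whi5)"),
    ("dep_whi5", {"Whi5_p": -1, "Whi5": 1},
     "(kdp_whi5_basal + kdp_whi5_cdc14 * Cdc14_p) * Whi5_p / (Km_whi5p + Whi5_p)"),
    ("bind_sbf_whi5", {"SBF": -1, "Whi5": -1, "SBF_Whi5": 1},
     "ka_sbf_whi5 * SBF * Whi5"),
    # Clb2 inactivates SBF; Cdc14 reverses it for the next G1
    ("pho_sbf", {"SBF": -1, "SBF_p": 1},
     "kp_sbf_clb2 * Clb2 * SBF / (Km_sbf + SBF)"),
    ("dep_sbf", {"SBF_p": -1, "SBF": 1},
     "(kdp_sbf_basal + kdp_sbf_cdc14 * Cdc14_p) * SBF_p / (Km_sbfp + SBF_p)"),
    # MBF activation by Cdc28-Cln1/2 (Whi5-independent route); cooperative
    # in the kinase signal, so MBF flips on sharply at the end of G1
    ("act_mbf", {"MBF": -1, "MBF_a": 1},
     "ka_mbf_cln2 * Cln2**2 / (Km_mbf**2 + Cln2**2) * MBF"),
    ("ina_mbf", {"MBF_a": -1, "MBF": 1},
     "ki_mbf * MBF_a / (Km_mbfa + MBF_a)"),
    # Mcm1 activation by Clb3 (S-phase timer) and Clb2 (positive feedback);
    # the inactive complement is Mcm1_tot - Mcm1_a
    ("act_mcm1", {"Mcm1_a": 1},
     "(ka_mcm1_basal + ka_mcm1_clb3 * Clb3**2 / (Km_mcm1**2 + Clb3**2)"
     " + ka_mcm1_clb2 * Clb2**2 / (Km_mcm1**2 + Clb2**2))"
     " * (Mcm1_tot - Mcm1_a)"),
    ("ina_mcm1", {"Mcm1_a": -1}, "ki_mcm1 * Mcm1_a / (Km_mcm1a + Mcm1_a)"),
    # APC activation by Mcm1 (stands for Mcm1-driven CDC20 expression) and by
    # Cdc14 (stands for Cdh1 dephosphorylation), which latches APC through
    # mitotic exit; Km_swi5 doubles as the shared Cdc14 mitotic-exit threshold
    ("act_apc", {"APC_a": 1},
     "(ka_apc_basal + ka_apc_mcm1 * Mcm1_a**2 / (Km_apc**2 + Mcm1_a**2)"
     " + ka_apc_cdc14 * Cdc14_p**2 / (Km_swi5**2 + Cdc14_p**2))"
     " * (APC_tot - APC_a)"),
    ("ina_apc", {"APC_a": -1}, "ki_apc * APC_a / (Km_apca + APC_a)"),
    # Sic1 phosphorylation by Cln2/Clb5 (targets it for degradation),
    # reversal by Cdc14, and the Hog1 stabilising phosphorylation (Thr173)
    ("pho_sic1", {"Sic1": -1, "Sic1_p": 1},
     "(kp_sic1_cln2 * Cln2 + kp_sic1_clb5 * Clb5) * Sic1 / (Km_sic1 + Sic1)"),
    ("dep_sic1", {"Sic1_p": -1, "Sic1": 1},
     "kdp_sic1_cdc14 * Cdc14_p * Sic1_p / (Km_sic1p + Sic1_p)"),
    ("hog_pho_sic1", {"Sic1": -1, "Sic1_Hp": 1},
     "HOG1 * kp_sic1_hog1 * Sic1 / (Km_sic1h + Sic1)"),
    ("dep_sic1_hp", {"Sic1_Hp": -1, "Sic1": 1}, "kdp_sic1_hp * Sic1_Hp"),
    ("hog_pho_clb5_sic1", {"Clb5_Sic1": -1, "Clb5_Sic1_Hp": 1},
     "HOG1 * kp_sic1c_hog1 * Clb5_Sic1"),
    ("dep_clb5_sic1_hp", {"Clb5_Sic1_Hp": -1, "Clb5_Sic1": 1},
     "kdp_sic1_hp * Clb5_Sic1_Hp"),
    # stoichiometric CKI binding of the Clb kinases by Sic1
    ("bind_clb5_sic1", {"Clb5": -1, "Sic1": -1, "Clb5_Sic1": 1},
     "kas_clb5_sic1 * Clb5 * Sic1"),
    ("rel_clb5_sic1", {"Clb5_Sic1": -1, "Clb5": 1, "Sic1": 1},
     "kdi_clb5_sic1 * Clb5_Sic1"),
    ("bind_clb5_sic1_hp", {"Clb5": -1, "Sic1_Hp": -1, "Clb5_Sic1_Hp": 1},
     "kas_clb5_sic1h * Clb5 * Sic1_Hp"),
    ("rel_clb5_sic1_hp", {"Clb5_Sic1_Hp": -1, "Clb5": 1, "Sic1_Hp": 1},
     "kdi_clb5_sic1h * Clb5_Sic1_Hp"),
    ("bind_clb3_sic1", {"Clb3": -1, "Sic1": -1, "Clb3_Sic1": 1},
     "kas_clb3_sic1 * Clb3 * Sic1"),
    ("rel_clb3_sic1", {"Clb3_Sic1": -1, "Clb3": 1, "Sic1": 1},
     "kdi_clb3_sic1 * Clb3_Sic1"),
    ("bind_clb2_sic1", {"Clb2": -1, "Sic1": -1, "Clb2_Sic1": 1},
     "kas_clb2_sic1 * Clb2 * Sic1"),
    ("rel_clb2_sic1", {"Clb2_Sic1": -1, "Clb2": 1, "Sic1": 1},
     "kdi_clb2_sic1 * Clb2_Sic1"),
    # Swe1/Clb2 mutual antagonism with Mih1 reversal; Hog1 blocks the
    # Clb2-mediated Swe1 phosphorylation
    ("pho_clb2", {"Clb2": -1, "Clb2_p": 1},
     "kp_clb2_swe1 * Swe1 * Clb2 / (Km_clb2 + Clb2)"),
    ("dep_clb2", {"Clb2_p": -1, "Clb2": 1},
     "kdp_clb2_mih1 * Mih1 * Clb2_p / (Km_clb2p + Clb2_p)"),
    ("pho_swe1", {"Swe1": -1, "Swe1_p": 1},
     "kp_swe1_clb2 * Clb2 * Swe1 / ((Km_swe1 + Swe1) * (1 + HOG1 * kh_swe1))"),
    ("dep_swe1", {"Swe1_p": -1, "Swe1": 1},
     "kdp_swe1 * Swe1_p / (Km_swe1p + Swe1_p)"),
    # Clb2 phosphorylates Net1, releasing Cdc14; Cdc14 self-amplifies (MEN)
    # and is additionally activated by APC
    ("pho_net1", {"Net1": -1, "Net1_p": 1},
     "kp_net1_clb2 * Clb2 * Net1 / (Km_net1 + Net1)"),
    ("dep_net1", {"Net1_p": -1, "Net1": 1},
     "kdp_net1 * Net1_p / (Km_net1p + Net1_p)"),
    ("act_cdc14", {"Cdc14": -1, "Cdc14_p": 1},
     "(ka_cdc14_net1 * Net1_p + ka_cdc14_apc * APC_a + ka_cdc14_self * Cdc14_p)"
     " * Cdc14 / (Km_cdc14 + Cdc14)"),
    ("ina_cdc14", {"Cdc14_p": -1, "Cdc14": 1},
     "ki_cdc14 * Cdc14_p / (Km_cdc14p + Cdc14_p)"),
    # Swi5 activation by Cdc14 (drives SIC1 expression)
    ("act_swi5", {"Swi5_a": 1},
     "ka_swi5_cdc14 * Cdc14_p**2 / (Km_swi5**2 + Cdc14_p**2)"
     " * (Swi5_tot - Swi5_a)"),
    ("ina_swi5", {"Swi5_a": -1}, "ki_swi5 * Swi5_a / (Km_swi5a + Swi5_a)"),
    # pheromone interface: Fus3 stabilises Far1 (Thr306 -> Far1_p), which
    # sequesters the Cln kinases; Cln2 phosphorylation (S87) degrades both forms
    ("pho_far1", {"Far1": -1, "Far1_p": 1},
     "FUS3 * kp_far1_fus3 * Far1 / (Km_far1 + Far1)"),
    ("dep_far1", {"Far1_p": -1, "Far1": 1}, "kdp_far1 * Far1_p"),
    ("bind_cln2_far1", {"Cln2": -1, "Far1_p": -1, "Cln2_Far1_p": 1},
     "kas_cln2_far1 * Cln2 * Far1_p"),
    ("rel_cln2_far1", {"Cln2_Far1_p": -1, "Cln2": 1, "Far1_p": 1},
     "kdi_cln2_far1 * Cln2_Far1_p"),
    ("bind_cln3_far1", {"Cln3": -1, "Far1_p": -1, "Cln3_Far1_p": 1},
     "kas_cln3_far1 * Cln3 * Far1_p"),
    ("rel_cln3_far1", {"Cln3_Far1_p": -1, "Cln3": 1, "Far1_p": 1},
     "kdi_cln3_far1 * Cln3_Far1_p"),
]

REACTION_NAMES = [r[0] for r in REACTIONS]

# canonical parameter order; the protein-production subset comes first
PRODUCTION_PARAMETERS = (
    "ks_cln3", "ks_cln2", "ks_clb5", "ks_clb3", "ks_clb2",
    "ks_sic1", "ks_sic1_swi5", "ks_swe1", "ks_far1", "ks_far1_fus3",
)

OTHER_PARAMETERS = (
    # signal fold-change / stress parameters
    "kh_cln2", "kh_clb5", "kh_swe1",
    # degradation
    "kd_cln3", "kd_cln2", "kd_clb5", "kd_clb5_apc", "kd_clb3", "kd_clb3_apc",
    "kd_clb2", "kd_clb2_apc", "kd_sic1", "kd_sic1p", "kd_swe1", "kd_swe1p",
    "kd_far1", "kd_far1p", "kd_far1_cln2",
    # complexed-Sic1 destruction
    "kp_sic1c_cln2", "kp_sic1c_clb5", "kp_sic1c_hog1",
    # Whi5 / SBF module
    "kp_whi5_cln3", "kp_whi5_cln2", "Km_whi5",
    "kp_sbfwhi5_cln3", "kp_sbfwhi5_cln2", "Km_sbfwhi5",
    "kdp_whi5_basal", "kdp_whi5_cdc14", "Km_whi5p", "ka_sbf_whi5",
    "kp_sbf_clb2", "Km_sbf", "kdp_sbf_basal", "kdp_sbf_cdc14", "Km_sbfp",
    # MBF
    "ka_mbf_cln2", "Km_mbf", "ki_mbf", "Km_mbfa",
    # Mcm1
    "ka_mcm1_basal", "ka_mcm1_clb3", "ka_mcm1_clb2", "Km_mcm1",
    "ki_mcm1", "Km_mcm1a", "Mcm1_tot",
    # APC
    "ka_apc_basal", "ka_apc_mcm1", "ka_apc_cdc14", "Km_apc", "ki_apc",
    "Km_apca", "APC_tot",
    # Sic1 phosphorylation states
    "kp_sic1_cln2", "kp_sic1_clb5", "Km_sic1", "kdp_sic1_cdc14", "Km_sic1p",
    "kp_sic1_hog1", "Km_sic1h", "kdp_sic1_hp",
    # CKI binding
    "kas_clb5_sic1", "kdi_clb5_sic1", "kas_clb5_sic1h", "kdi_clb5_sic1h",
    "kas_clb3_sic1", "kdi_clb3_sic1", "kas_clb2_sic1", "kdi_clb2_sic1",
    # Swe1 / Clb2 switch
    "kp_clb2_swe1", "Km_clb2", "kdp_clb2_mih1", "Mih1", "Km_clb2p",
    "kp_swe1_clb2", "Km_swe1", "kdp_swe1", "Km_swe1p",
    # Net1 / Cdc14 / mitotic exit
    "kp_net1_clb2", "Km_net1", "kdp_net1", "Km_net1p",
    "ka_cdc14_net1", "ka_cdc14_apc", "ka_cdc14_self", "Km_cdc14",
    "ki_cdc14", "Km_cdc14p",
    # Swi5
    "ka_swi5_cdc14", "Km_swi5", "ki_swi5", "Km_swi5a", "Swi5_tot",
    # Far1 / pheromone interface
    "kp_far1_fus3", "Km_far1", "kdp_far1",
    "kas_cln2_far1", "kdi_cln2_far1", "kas_cln3_far1", "kdi_cln3_far1",
)

PARAMETERS = PRODUCTION_PARAMETERS + OTHER_PARAMETERS
PARAMETER_INDEX = {name: i for i, name in enumerate(PARAMETERS)}
N_PARAMETERS = len(PARAMETERS)

SIGNAL_NAMES = ("FUS3", "HOG1", "NU")


def _build_stoichiometry():
    import numpy as np

    n = np.zeros((N_SPECIES, len(REACTIONS)))
    for j, (_, stoich, _) in enumerate(REACTIONS):
        for species, coeff in stoich.items():
            n[SPECIES_INDEX[species], j] = coeff
    return n


def compile_rates(species=SPECIES, parameters=PARAMETERS, expressions=None):
    """Compile reaction-rate expressions into one numpy function.

    Returns ``rates(y, p, FUS3, HOG1, NU) -> ndarray`` of per-reaction
    fluxes.  The generated code unpacks species and parameters into locals
    so each expression string is evaluated exactly as written.
    """
    if expressions is None:
        expressions = [expr for _, _, expr in REACTIONS]
    lines = ["def _rates(y, p, FUS3, HOG1, NU):"]
    for i, name in enumerate(species):
        lines.append(f"    {name} = y[{i}]")
    for i, name in enumerate(parameters):
        lines.append(f"    {name} = p[{i}]")
    exprs = ",\n        ".join(expressions)
    lines.append(f"    return _np.array([\n        {exprs}\n    ])")
    source = "\n".join(lines)
    import numpy as _np

    namespace = {"_np": _np}
    exec(compile(source, "<yeastcycle-rates>", "exec"), namespace)
    return namespace["_rates"]
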