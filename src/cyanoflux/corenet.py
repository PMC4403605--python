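"""Synthetic core phototrophic network generator.

This module programmatically builds a curated, fully elementally balanced core
model of cyanobacterial photoautotrophic metabolism so that every pipeline
stage (yield accounting, trade-off scans, transition experiments) runs without
any external model file.  The core emulates the stoichiometric structure the
analysis assumes:

* photosynthetic light reactions with 1 photon per electron at each
  photosystem, water splitting releasing 1 lumen H+ per electron, a cytochrome
  b6f Q-cycle translocating 2 H+ per electron, PSI reduction of ferredoxin,
  FNR, cyclic electron flow, NDH-1, and an ATP synthase importing 14/3 lumen
  H+ per ATP — under linear electron flow this yields exactly 9/7 ATP per
  NADPH;
* the Calvin–Benson–Bassham cycle with separable Rubisco carboxylase and
  oxygenase reactions, lower glycolysis (ENO, PYK, PPS), phosphoketolase and
  phosphotransacetylase, pyruvate dehydrogenase and the (incomplete,
  2-oxoglutarate-dehydrogenase-free) cyanobacterial TCA reactions;
* cost-free Na+-dependent bicarbonate uptake alongside an ATP-dependent
  transporter, carbonic anhydrase, GS-GOGAT nitrogen assimilation from
  nitrate or ammonium, NAD(P)H transhydrogenation, maintenance ATP
  hydrolysis, and Mehler-like / ROS pseudo-sinks used by the wild-type-state
  constraint preset.

Extension packs add precursor metabolism for the twelve bioproducts:
``fermentative`` (acetolactate/ketoisovalerate branch and the acetoacetyl-CoA
trunk), ``isoprenoid_mep`` (MEP pathway to DMAPP), ``fatty_acid`` (acyl-ACP
synthesis to C16/C18), ``arginine_tca`` (arginine biosynthesis and
pyrroline-5-carboxylate recycling) and ``photorespiration`` (bacterial
glycerate pathway for glycolate salvage).

The generated network is deterministic: the same spec always yields a
byte-identical serialization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

from .exceptions import StructuralError
from .io import parse_equation
from .model import MetabolicModel, Metabolite, Reaction, parse_formula

EXTENSIONS = ("fermentative", "isoprenoid_mep", "fatty_acid", "arginine_tca",
              "photorespiration")

#: photon energy at 680 nm, kJ per mol photons
PHOTON_ENERGY_680NM = 175.9


@dataclass(frozen=True)
class CoreNetworkSpec:
    """Parameters of the synthetic core network.

    The light-reaction stoichiometry parameters are the knobs that set the
    ATP/NADPH output ratio of the linear electron chain: with 1 photon per
    electron per photosystem, 1 lumen H+ per electron from water oxidation,
    2 H+ per electron from the b6f Q-cycle, and 14/3 H+ per ATP, linear flow
    delivers 6 lumen H+ per NADPH, i.e. 9/7 ~ 1.29 ATP per NADPH.
    """

    extensions: tuple[str, ...] = ()
    include_toy_biomass: bool = False
    atp_synthase_h_per_atp: Fraction = Fraction(14, 3)
    qcycle_h_per_electron: int = 2
    oec_h_per_electron: int = 1
    photons_per_electron_per_photosystem: int = 1
    ndh_h_per_electron: int = 2
    photon_energy_680nm: float = PHOTON_ENERGY_680NM

    def __post_init__(self):
        for ext in self.extensions:
            if ext not in EXTENSIONS:
                raise StructuralError(
                    f"unknown extension {ext!r}; valid: {', '.join(EXTENSIONS)}")
        for name in ("atp_synthase_h_per_atp", "qcycle_h_per_electron",
                     "oec_h_per_electron", "photons_per_electron_per_photosystem",
                     "ndh_h_per_electron", "photon_energy_680nm"):
            if getattr(self, name) <= 0:
                raise StructuralError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# metabolite catalog (single source of truth, shared with the pathway library)
# ---------------------------------------------------------------------------
# (id, name, formula)  -- formula None marks a pseudo-species (photon, biomass),
# "" marks an elementally null pool carrier (redox pairs differing by electrons
# only; protons are tracked explicitly).

METABOLITE_CATALOG: dict[str, tuple[str, str | None]] = {
    # external
    "photon_e": ("photon", None),
    "hco3_e": ("bicarbonate", "CHO3"),
    "co2_e": ("CO2", "CO2"),
    "o2_e": ("O2", "O2"),
    "h2o_e": ("water", "H2O"),
    "h_e": ("proton", "H"),
    "nh4_e": ("ammonium", "H4N"),
    "no3_e": ("nitrate", "NO3"),
    "glyclt_e": ("glycolate", "C2H3O3"),
    "pi_e": ("orthophosphate", "HO4P"),
    # thylakoid lumen
    "h_l": ("proton (lumen)", "H"),
    # cytoplasm: small inorganics and cofactors
    "h_c": ("proton", "H"),
    "h2o_c": ("water", "H2O"),
    "o2_c": ("O2", "O2"),
    "co2_c": ("CO2", "CO2"),
    "hco3_c": ("bicarbonate", "CHO3"),
    "pi_c": ("orthophosphate", "HO4P"),
    "ppi_c": ("diphosphate", "HO7P2"),
    "atp_c": ("ATP", "C10H12N5O13P3"),
    "adp_c": ("ADP", "C10H12N5O10P2"),
    "amp_c": ("AMP", "C10H12N5O7P"),
    "nad_c": ("NAD+", "C21H26N7O14P2"),
    "nadh_c": ("NADH", "C21H27N7O14P2"),
    "nadp_c": ("NADP+", "C21H25N7O17P3"),
    "nadph_c": ("NADPH", "C21H26N7O17P3"),
    "coa_c": ("coenzyme A", "C21H32N7O16P3S"),
    "accoa_c": ("acetyl-CoA", "C23H34N7O17P3S"),
    # electron carriers (elementally null pools; H tracked via explicit protons)
    "pq_c": ("plastoquinone", ""),
    "pqh2_c": ("plastoquinol", "H2"),
    "pc_ox_c": ("plastocyanin (ox)", ""),
    "pc_red_c": ("plastocyanin (red)", ""),
    "fd_ox_c": ("ferredoxin (ox)", ""),
    "fd_red_c": ("ferredoxin (red)", ""),
    # CBB cycle and lower glycolysis
    "rb15bp_c": ("ribulose-1,5-bisphosphate", "C5H8O11P2"),
    "pg3_c": ("3-phosphoglycerate", "C3H4O7P"),
    "pg2_c": ("2-phosphoglycerate", "C3H4O7P"),
    "dpg13_c": ("1,3-bisphosphoglycerate", "C3H4O10P2"),
    "gap_c": ("glyceraldehyde 3-phosphate", "C3H5O6P"),
    "dhap_c": ("dihydroxyacetone phosphate", "C3H5O6P"),
    "fdp_c": ("fructose 1,6-bisphosphate", "C6H10O12P2"),
    "f6p_c": ("fructose 6-phosphate", "C6H11O9P"),
    "e4p_c": ("erythrose 4-phosphate", "C4H7O7P"),
    "x5p_c": ("xylulose 5-phosphate", "C5H9O8P"),
    "r5p_c": ("ribose 5-phosphate", "C5H9O8P"),
    "ru5p_c": ("ribulose 5-phosphate", "C5H9O8P"),
    "s17bp_c": ("sedoheptulose 1,7-bisphosphate", "C7H12O13P2"),
    "s7p_c": ("sedoheptulose 7-phosphate", "C7H13O10P"),
    "pglyc_c": ("2-phosphoglycolate", "C2H2O6P"),
    "glyclt_c": ("glycolate", "C2H3O3"),
    "pep_c": ("phosphoenolpyruvate", "C3H2O6P"),
    "pyr_c": ("pyruvate", "C3H3O3"),
    "actp_c": ("acetyl phosphate", "C2H3O5P"),
    "for_c": ("formate", "CHO2"),
    # TCA
    "cit_c": ("citrate", "C6H5O7"),
    "icit_c": ("isocitrate", "C6H5O7"),
    "akg_c": ("2-oxoglutarate", "C5H4O5"),
    "succ_c": ("succinate", "C4H4O4"),
    "fum_c": ("fumarate", "C4H2O4"),
    "mal_c": ("malate", "C4H4O5"),
    "oaa_c": ("oxaloacetate", "C4H2O5"),
    # nitrogen
    "nh4_c": ("ammonium", "H4N"),
    "no3_c": ("nitrate", "NO3"),
    "no2_c": ("nitrite", "NO2"),
    "glu_c": ("glutamate", "C5H8NO4"),
    "gln_c": ("glutamine", "C5H10N2O3"),
    # biomass pseudo-species
    "biomass_c": ("biomass", None),
    # fermentative pack
    "lac_c": ("lactate", "C3H5O3"),
    "acald_c": ("acetaldehyde", "C2H4O"),
    "etoh_c": ("ethanol", "C2H6O"),
    "alac_c": ("2-acetolactate", "C5H7O4"),
    "dhiv_c": ("2,3-dihydroxy-3-methylbutanoate", "C5H9O4"),
    "mob_c": ("3-methyl-2-oxobutanoate", "C5H7O3"),
    "ibal_c": ("isobutyraldehyde", "C4H8O"),
    "ibtoh_c": ("isobutanol", "C4H10O"),
    "actn_c": ("(R)-acetoin", "C4H8O2"),
    "btd_c": ("(R,R)-butane-2,3-diol", "C4H10O2"),
    "aacoa_c": ("acetoacetyl-CoA", "C25H36N7O18P3S"),
    "hbcoa_c": ("(R)-3-hydroxybutanoyl-CoA", "C25H38N7O18P3S"),
    "b2coa_c": ("crotonoyl-CoA", "C25H36N7O17P3S"),
    "btcoa_c": ("butanoyl-CoA", "C25H38N7O17P3S"),
    "btal_c": ("butyraldehyde", "C4H8O"),
    "btoh_c": ("1-butanol", "C4H10O"),
    "prop_c": ("propane", "C3H8"),
    # isoprenoid (MEP) pack
    "dxp_c": ("1-deoxy-D-xylulose 5-phosphate", "C5H9O7P"),
    "mep_c": ("2-C-methyl-D-erythritol 4-phosphate", "C5H11O7P"),
    "mecdp_c": ("2-C-methyl-D-erythritol 2,4-cyclodiphosphate", "C5H9O9P2"),
    "hmbpp_c": ("1-hydroxy-2-methyl-2-butenyl 4-diphosphate", "C5H9O8P2"),
    "dmapp_c": ("dimethylallyl diphosphate", "C5H9O7P2"),
    "iprn_c": ("isoprene", "C5H8"),
    # fatty-acid pack (acyl moieties on an elementally null ACP carrier)
    "acp_c": ("acyl carrier protein", ""),
    "malcoa_c": ("malonyl-CoA", "C24H33N7O19P3S"),
    "malacp_c": ("malonyl-ACP", "C3HO3"),
    "acp2_c": ("acetyl-ACP", "C2H2O"),
    "acp4_c": ("butanoyl-ACP", "C4H6O"),
    "acp6_c": ("hexanoyl-ACP", "C6H10O"),
    "acp8_c": ("octanoyl-ACP", "C8H14O"),
    "acp10_c": ("decanoyl-ACP", "C10H18O"),
    "acp12_c": ("dodecanoyl-ACP", "C12H22O"),
    "acp14_c": ("tetradecanoyl-ACP", "C14H26O"),
    "acp16_c": ("hexadecanoyl-ACP", "C16H30O"),
    "acp18_c": ("octadecanoyl-ACP", "C18H34O"),
    "hdcal_c": ("hexadecanal", "C16H32O"),
    "ocdcal_c": ("octadecanal", "C18H36O"),
    "ocdcol_c": ("1-octadecanol", "C18H38O"),
    "hpdcn_c": ("heptadecane", "C17H36"),
    "pntdcn_c": ("pentadecane", "C15H32"),
    # arginine / ethylene pack
    "asp_c": ("aspartate", "C4H6NO4"),
    "acglu_c": ("N-acetylglutamate", "C7H9NO5"),
    "acg5sa_c": ("N-acetylglutamate 5-semialdehyde", "C7H11NO4"),
    "acorn_c": ("N-acetylornithine", "C7H15N2O3"),
    "orn_c": ("ornithine", "C5H13N2O2"),
    "cbp_c": ("carbamoyl phosphate", "CH2NO5P"),
    "citr_c": ("citrulline", "C6H13N3O3"),
    "argsuc_c": ("argininosuccinate", "C10H17N4O6"),
    "arg_c": ("arginine", "C6H15N4O2"),
    "p5c_c": ("(S)-1-pyrroline-5-carboxylate", "C5H6NO2"),
    "ethl_c": ("ethylene", "C2H4"),
    "gdn_c": ("guanidine", "CH5N3"),
    "urea_c": ("urea", "CH4N2O"),
    # photorespiration pack
    "glx_c": ("glyoxylate", "C2HO3"),
    "tsa_c": ("tartronate semialdehyde", "C3H3O4"),
    "glycr_c": ("D-glycerate", "C3H5O4"),
    # product externals (added on demand by augmentation)
    "etoh_e": ("ethanol", "C2H6O"),
    "lac_e": ("lactate", "C3H5O3"),
    "ethl_e": ("ethylene", "C2H4"),
    "prop_e": ("propane", "C3H8"),
    "btoh_e": ("1-butanol", "C4H10O"),
    "iprn_e": ("isoprene", "C5H8"),
    "ocdcol_e": ("1-octadecanol", "C18H38O"),
    "hpdcn_e": ("heptadecane", "C17H36"),
    "pntdcn_e": ("pentadecane", "C15H32"),
    "btd_e": ("(R,R)-butane-2,3-diol", "C4H10O2"),
    "ibal_e": ("isobutyraldehyde", "C4H8O"),
    "ibtoh_e": ("isobutanol", "C4H10O"),
    "gdn_e": ("guanidine", "CH5N3"),
}


def make_metabolite(met_id: str) -> Metabolite:
    """Instantiate a catalog metabolite (compartment from the id suffix)."""
    try:
        name, formula = METABOLITE_CATALOG[met_id]
    except KeyError:
        raise StructuralError(f"metabolite {met_id!r} not in catalog") from None
    compartment = met_id.rsplit("_", 1)[-1]
    return Metabolite(met_id, name=name, compartment=compartment,
                      formula=None if formula is None else parse_formula(formula))


# ---------------------------------------------------------------------------
# reaction tables
# ---------------------------------------------------------------------------
# (id, name, equation, lb, ub, subsystem, pseudo)

_INF = 1000.0


def _base_reactions(spec: CoreNetworkSpec) -> list[tuple]:
    ppe = spec.photons_per_electron_per_photosystem
    oec = spec.oec_h_per_electron
    qcy = spec.qcycle_h_per_electron
    ndh = spec.ndh_h_per_electron
    hpa = spec.atp_synthase_h_per_atp
    rows = [
        # exchanges (pseudo: one-sided by design)
        ("EX_photon", "photon exchange", "photon_e =>", -_INF, 0.0, "exchange", True),
        ("EX_hco3", "bicarbonate exchange", "hco3_e =>", -_INF, _INF, "exchange", True),
        ("EX_co2", "CO2 exchange", "co2_e =>", -_INF, _INF, "exchange", True),
        ("EX_o2", "O2 exchange", "o2_e =>", -_INF, _INF, "exchange", True),
        ("EX_h2o", "water exchange", "h2o_e =>", -_INF, _INF, "exchange", True),
        ("EX_h", "proton exchange", "h_e =>", -_INF, _INF, "exchange", True),
        ("EX_nh4", "ammonium exchange", "nh4_e =>", 0.0, _INF, "exchange", True),
        ("EX_no3", "nitrate exchange", "no3_e =>", -_INF, _INF, "exchange", True),
        ("EX_glyclt", "glycolate excretion", "glyclt_e =>", 0.0, _INF, "exchange", True),
        ("EX_pi", "phosphate exchange", "pi_e =>", -_INF, _INF, "exchange", True),
        # transport
        ("T_pi", "phosphate uptake", "pi_e => pi_c", 0.0, _INF, "transport", False),
        ("T_hco3_na", "Na+-dependent bicarbonate uptake (cost-free)",
         "hco3_e => hco3_c", 0.0, _INF, "transport", False),
        ("T_hco3_atp", "ATP-dependent bicarbonate uptake",
         "hco3_e + atp_c + h2o_c => hco3_c + adp_c + pi_c + h_c",
         0.0, _INF, "transport", False),
        ("T_co2", "CO2 diffusion", "co2_e <=> co2_c", -_INF, _INF, "transport", False),
        ("T_o2", "O2 diffusion", "o2_c <=> o2_e", -_INF, _INF, "transport", False),
        ("T_h2o", "water transport", "h2o_c <=> h2o_e", -_INF, _INF, "transport", False),
        ("T_h", "proton exchange (plasma membrane)", "h_c <=> h_e",
         -_INF, _INF, "transport", False),
        ("T_no3", "nitrate uptake", "no3_e => no3_c", 0.0, _INF, "transport", False),
        ("T_nh4", "ammonium uptake", "nh4_e => nh4_c", 0.0, _INF, "transport", False),
        ("T_glyclt", "glycolate export", "glyclt_c => glyclt_e",
         0.0, _INF, "transport", False),
        # photosynthetic light reactions (per 2 electrons unless noted)
        ("PSII", "photosystem II incl. water splitting",
         f"{2 * ppe} photon_e + h2o_c + pq_c + 2 h_c => "
         f"pqh2_c + 1/2 o2_c + {2 * oec} h_l",
         0.0, _INF, "light", True),
        ("B6F", "cytochrome b6f complex incl. Q-cycle",
         f"pqh2_c + 2 pc_ox_c + {2 * qcy - 2} h_c => pq_c + 2 pc_red_c + {2 * qcy} h_l",
         0.0, _INF, "light", False),
        ("B6F0", "cytochrome b6f complex (Q-cycle bypassed)",
         "pqh2_c + 2 pc_ox_c => pq_c + 2 pc_red_c + 2 h_l",
         0.0, _INF, "light", False),
        ("PSI", "photosystem I (per electron)",
         f"{ppe} photon_e + pc_red_c + fd_ox_c => pc_ox_c + fd_red_c",
         0.0, _INF, "light", True),
        ("FNR", "ferredoxin-NADP+ reductase",
         "2 fd_red_c + nadp_c + h_c => 2 fd_ox_c + nadph_c",
         0.0, _INF, "light", False),
        ("CEF", "cyclic electron flow around PSI",
         "2 fd_red_c + pq_c + 2 h_c => 2 fd_ox_c + pqh2_c",
         0.0, _INF, "light", False),
        ("NDH1", "NDH-1 complex (NADPH -> PQ, proton pumping)",
         f"nadph_c + {2 * ndh + 1} h_c + pq_c => nadp_c + pqh2_c + {2 * ndh} h_l",
         0.0, _INF, "light", False),
        ("ATPS", "thylakoid ATP synthase",
         f"adp_c + pi_c + {hpa} h_l => atp_c + h2o_c + {hpa - 1} h_c",
         0.0, _INF, "light", False),
        ("LEAK", "passive lumen proton leak", "h_l => h_c",
         0.0, _INF, "light", False),
        ("COX", "cytochrome c oxidase (respiration, 1 H+ pumped per electron)",
         "4 pc_red_c + o2_c + 8 h_c => 4 pc_ox_c + 2 h2o_c + 4 h_l",
         0.0, _INF, "respiration", False),
        ("MEHLER", "Mehler-like reaction (flavodiiron O2 reduction)",
         "4 fd_red_c + 4 h_c + o2_c => 4 fd_ox_c + 2 h2o_c",
         0.0, _INF, "alternative electron flow", False),
        ("ROSPSII", "ROS formation and detoxification at PSII (lumped)",
         "pqh2_c + 1/2 o2_c => pq_c + h2o_c",
         0.0, _INF, "alternative electron flow", False),
        ("ROSPSI", "ROS formation and detoxification at PSI/Mehler (lumped)",
         "2 fd_red_c + 2 h_c + 1/2 o2_c => 2 fd_ox_c + h2o_c",
         0.0, _INF, "alternative electron flow", False),
        ("MAINT", "growth-independent maintenance ATP hydrolysis",
         "atp_c + h2o_c => adp_c + pi_c + h_c",
         0.0, _INF, "maintenance", False),
        # carbon-concentrating mechanism
        ("CA", "carbonic anhydrase", "hco3_c + h_c <=> co2_c + h2o_c",
         -_INF, _INF, "CCM", False),
        # Calvin-Benson-Bassham cycle; carboxylase and oxygenase are separate
        # reactions so they can be left decoupled or ratio-coupled by scenarios
        ("RBC_carb", "Rubisco carboxylase",
         "rb15bp_c + co2_c + h2o_c => 2 pg3_c + 2 h_c", 0.0, _INF, "CBB", False),
        ("RBC_oxy", "Rubisco oxygenase",
         "rb15bp_c + o2_c => pg3_c + pglyc_c + 2 h_c", 0.0, _INF, "CBB", False),
        ("PGLP", "phosphoglycolate phosphatase",
         "pglyc_c + h2o_c => glyclt_c + pi_c", 0.0, _INF, "CBB", False),
        ("PGK", "phosphoglycerate kinase",
         "pg3_c + atp_c <=> dpg13_c + adp_c", -_INF, _INF, "CBB", False),
        ("GAPDH", "glyceraldehyde-3-phosphate dehydrogenase (NADPH)",
         "dpg13_c + nadph_c + h_c <=> gap_c + nadp_c + pi_c",
         -_INF, _INF, "CBB", False),
        ("TPI", "triose-phosphate isomerase", "gap_c <=> dhap_c",
         -_INF, _INF, "CBB", False),
        ("FBA", "fructose-bisphosphate aldolase", "gap_c + dhap_c <=> fdp_c",
         -_INF, _INF, "CBB", False),
        ("FBP", "fructose-1,6-bisphosphatase", "fdp_c + h2o_c => f6p_c + pi_c",
         0.0, _INF, "CBB", False),
        ("TKT1", "transketolase (F6P + GAP)", "f6p_c + gap_c <=> x5p_c + e4p_c",
         -_INF, _INF, "CBB", False),
        ("SBA", "sedoheptulose-bisphosphate aldolase",
         "e4p_c + dhap_c <=> s17bp_c", -_INF, _INF, "CBB", False),
        ("SBP", "sedoheptulose-1,7-bisphosphatase",
         "s17bp_c + h2o_c => s7p_c + pi_c", 0.0, _INF, "CBB", False),
        ("TKT2", "transketolase (S7P + GAP)", "s7p_c + gap_c <=> r5p_c + x5p_c",
         -_INF, _INF, "CBB", False),
        ("RPI", "ribose-5-phosphate isomerase", "r5p_c <=> ru5p_c",
         -_INF, _INF, "CBB", False),
        ("RPE", "ribulose-phosphate 3-epimerase", "x5p_c <=> ru5p_c",
         -_INF, _INF, "CBB", False),
        ("PRK", "phosphoribulokinase", "ru5p_c + atp_c => rb15bp_c + adp_c + h_c",
         0.0, _INF, "CBB", False),
        # lower glycolysis
        ("PGM", "phosphoglycerate mutase", "pg3_c <=> pg2_c",
         -_INF, _INF, "glycolysis", False),
        ("ENO", "enolase", "pg2_c <=> pep_c + h2o_c", -_INF, _INF, "glycolysis", False),
        ("PYK", "pyruvate kinase", "pep_c + adp_c + h_c => pyr_c + atp_c",
         0.0, _INF, "glycolysis", False),
        ("PPS", "PEP synthase", "pyr_c + atp_c + h2o_c => pep_c + amp_c + pi_c + 2 h_c",
         0.0, _INF, "glycolysis", False),
        ("ADK", "adenylate kinase", "amp_c + atp_c <=> 2 adp_c",
         -_INF, _INF, "glycolysis", False),
        ("PPA", "inorganic pyrophosphatase", "ppi_c + h2o_c => 2 pi_c + h_c",
         0.0, _INF, "glycolysis", False),
        ("PKL1", "phosphoketolase (F6P)", "f6p_c + pi_c => e4p_c + actp_c + h2o_c",
         0.0, _INF, "phosphoketolase", False),
        ("PKL2", "phosphoketolase (X5P)", "x5p_c + pi_c => gap_c + actp_c + h2o_c",
         0.0, _INF, "phosphoketolase", False),
        ("PTA", "phosphotransacetylase", "accoa_c + pi_c <=> actp_c + coa_c",
         -_INF, _INF, "phosphoketolase", False),
        ("PDH", "pyruvate dehydrogenase",
         "pyr_c + coa_c + nad_c => accoa_c + co2_c + nadh_c",
         0.0, _INF, "glycolysis", False),
        ("FDH", "formate dehydrogenase", "for_c + nad_c => co2_c + nadh_c",
         0.0, _INF, "glycolysis", False),
        # TCA reactions (cyanobacterial, no 2-OG dehydrogenase)
        ("CS", "citrate synthase", "accoa_c + oaa_c + h2o_c => cit_c + coa_c + h_c",
         0.0, _INF, "TCA", False),
        ("ACO", "aconitase", "cit_c <=> icit_c", -_INF, _INF, "TCA", False),
        ("IDH", "isocitrate dehydrogenase (NADP)",
         "icit_c + nadp_c => akg_c + co2_c + nadph_c", 0.0, _INF, "TCA", False),
        ("SDH", "succinate dehydrogenase (PQ-coupled)",
         "succ_c + pq_c => fum_c + pqh2_c", 0.0, _INF, "TCA", False),
        ("FH", "fumarate hydratase", "fum_c + h2o_c <=> mal_c",
         -_INF, _INF, "TCA", False),
        ("MDH", "malate dehydrogenase", "mal_c + nad_c <=> oaa_c + nadh_c + h_c",
         -_INF, _INF, "TCA", False),
        ("ME", "malic enzyme (NADP)", "mal_c + nadp_c => pyr_c + co2_c + nadph_c",
         0.0, _INF, "TCA", False),
        ("PEPC", "PEP carboxylase", "pep_c + hco3_c => oaa_c + pi_c",
         0.0, _INF, "TCA", False),
        ("THD", "NAD(P) transhydrogenase", "nadh_c + nadp_c <=> nad_c + nadph_c",
         -_INF, _INF, "cofactor", False),
        # nitrogen assimilation
        ("NR", "nitrate reductase (NADH)",
         "no3_c + nadh_c + h_c => no2_c + nad_c + h2o_c", 0.0, _INF, "nitrogen", False),
        ("NIR", "nitrite reductase (ferredoxin)",
         "no2_c + 6 fd_red_c + 8 h_c => nh4_c + 2 h2o_c + 6 fd_ox_c",
         0.0, _INF, "nitrogen", False),
        ("GS", "glutamine synthetase",
         "glu_c + nh4_c + atp_c => gln_c + adp_c + pi_c + h_c",
         0.0, _INF, "nitrogen", False),
        ("GOGAT", "glutamate synthase (ferredoxin)",
         "akg_c + gln_c + 2 fd_red_c + 2 h_c => 2 glu_c + 2 fd_ox_c",
         0.0, _INF, "nitrogen", False),
    ]
    return rows


_FERMENTATIVE = [
    ("LDH", "lactate dehydrogenase", "pyr_c + nadh_c + h_c => lac_c + nad_c",
     0.0, _INF, "fermentative", False),
    ("ACALDDH", "acetaldehyde dehydrogenase (CoA-acylating; acetate-side route)",
     "accoa_c + nadh_c + h_c => acald_c + coa_c + nad_c",
     0.0, _INF, "fermentative", False),
    ("ALS", "acetolactate synthase", "2 pyr_c + h_c => alac_c + co2_c",
     0.0, _INF, "fermentative", False),
    ("KARI", "ketol-acid reductoisomerase",
     "alac_c + nadph_c + h_c => dhiv_c + nadp_c", 0.0, _INF, "fermentative", False),
    ("DHAD", "dihydroxy-acid dehydratase", "dhiv_c => mob_c + h2o_c",
     0.0, _INF, "fermentative", False),
    ("THL", "acetoacetyl-CoA thiolase", "2 accoa_c <=> aacoa_c + coa_c",
     -_INF, _INF, "fermentative", False),
    ("PHAB", "acetoacetyl-CoA reductase (R-specific, NADPH)",
     "aacoa_c + nadph_c + h_c => hbcoa_c + nadp_c", 0.0, _INF, "fermentative", False),
]

# The cytidylyl (CDP-ME) carrier of the MEP pathway is treated as catalytic:
# the synthase/kinase/cyclase segment is lumped into one ATP-consuming step.
_ISOPRENOID = [
    ("DXS", "1-deoxy-D-xylulose-5-phosphate synthase",
     "pyr_c + gap_c + h_c => dxp_c + co2_c", 0.0, _INF, "MEP pathway", False),
    ("DXR", "DXP reductoisomerase", "dxp_c + nadph_c + h_c => mep_c + nadp_c",
     0.0, _INF, "MEP pathway", False),
    ("MECDPS", "MEP cyclodiphosphate synthesis (lumped CMS/CMK/MDS)",
     "mep_c + atp_c => mecdp_c + adp_c + h2o_c", 0.0, _INF, "MEP pathway", False),
    ("ISPG", "HMBPP synthase (ferredoxin)",
     "mecdp_c + 2 fd_red_c + 2 h_c => hmbpp_c + h2o_c + 2 fd_ox_c",
     0.0, _INF, "MEP pathway", False),
    ("ISPH", "HMBPP reductase (ferredoxin)",
     "hmbpp_c + 2 fd_red_c + 2 h_c => dmapp_c + h2o_c + 2 fd_ox_c",
     0.0, _INF, "MEP pathway", False),
]

_FATTY_ACID = [
    ("ACC", "acetyl-CoA carboxylase",
     "accoa_c + hco3_c + atp_c => malcoa_c + adp_c + pi_c + h_c",
     0.0, _INF, "fatty acid", False),
    ("MAT", "malonyl-CoA:ACP transacylase", "malcoa_c + acp_c => malacp_c + coa_c",
     0.0, _INF, "fatty acid", False),
    ("FAT", "acetyl-CoA:ACP transacylase", "accoa_c + acp_c => acp2_c + coa_c",
     0.0, _INF, "fatty acid", False),
] + [
    (f"FAS{n + 2}", f"fatty-acid elongation C{n} -> C{n + 2} (lumped KS/KR/DH/ER)",
     f"acp{n}_c + malacp_c + 2 nadph_c + 3 h_c => "
     f"acp{n + 2}_c + acp_c + co2_c + 2 nadp_c + h2o_c",
     0.0, _INF, "fatty acid", False)
    for n in (2, 4, 6, 8, 10, 12, 14, 16)
]

_ARGININE = [
    ("AST", "aspartate aminotransferase", "oaa_c + glu_c <=> asp_c + akg_c",
     -_INF, _INF, "arginine", False),
    ("NAGS", "N-acetylglutamate synthase (priming)",
     "glu_c + accoa_c => acglu_c + coa_c + h_c", 0.0, _INF, "arginine", False),
    ("NAGK", "N-acetylglutamate kinase + reductase (lumped)",
     "acglu_c + atp_c + nadph_c + 2 h_c => acg5sa_c + adp_c + pi_c + nadp_c",
     0.0, _INF, "arginine", False),
    ("ACOTA", "acetylornithine aminotransferase",
     "acg5sa_c + glu_c <=> acorn_c + akg_c", -_INF, _INF, "arginine", False),
    ("OAT", "ornithine acetyltransferase (acetyl recycling)",
     "acorn_c + glu_c => orn_c + acglu_c + h_c", 0.0, _INF, "arginine", False),
    ("CPS", "carbamoyl-phosphate synthetase",
     "gln_c + hco3_c + 2 atp_c + h2o_c => cbp_c + 2 adp_c + pi_c + glu_c + 2 h_c",
     0.0, _INF, "arginine", False),
    ("OTC", "ornithine transcarbamylase",
     "orn_c + cbp_c => citr_c + pi_c + h_c", 0.0, _INF, "arginine", False),
    ("ASS", "argininosuccinate synthetase",
     "citr_c + asp_c + atp_c => argsuc_c + amp_c + ppi_c + h_c",
     0.0, _INF, "arginine", False),
    ("ASL", "argininosuccinate lyase", "argsuc_c <=> arg_c + fum_c",
     -_INF, _INF, "arginine", False),
    ("P5CD", "pyrroline-5-carboxylate -> glutamate (via semialdehyde, lumped)",
     "p5c_c + nad_c + 2 h2o_c => glu_c + nadh_c + h_c", 0.0, _INF, "arginine", False),
]

_PHOTORESPIRATION = [
    ("GLYCDH", "glycolate dehydrogenase (PQ-coupled)",
     "glyclt_c + pq_c => glx_c + pqh2_c", 0.0, _INF, "photorespiration", False),
    ("GCL", "glyoxylate carboligase", "2 glx_c + h_c => tsa_c + co2_c",
     0.0, _INF, "photorespiration", False),
    ("TSAR", "tartronate-semialdehyde reductase",
     "tsa_c + nadh_c + h_c => glycr_c + nad_c", 0.0, _INF, "photorespiration", False),
    ("GLYK", "glycerate kinase", "glycr_c + atp_c => pg3_c + adp_c + h_c",
     0.0, _INF, "photorespiration", False),
]

_EXTENSION_TABLES = {
    "fermentative": _FERMENTATIVE,
    "isoprenoid_mep": _ISOPRENOID,
    "fatty_acid": _FATTY_ACID,
    "arginine_tca": _ARGININE,
    "photorespiration": _PHOTORESPIRATION,
}

# toy biomass: drains triose, acetyl-CoA and glutamate plus growth-associated
# ATP; composition chosen so the implied ATP/NADPH demand clearly exceeds the
# 9/7 supply ratio of linear electron flow (growth is ATP-limited, as for real
# biomass synthesis)
BIOMASS_EQUATION = ("0.6 gap_c + 0.3 accoa_c + 0.25 glu_c + 5 atp_c + 5 h2o_c"
                    " => biomass_c + 0.3 coa_c + 5 adp_c + 5 pi_c + 5 h_c")


def _add_rows(model: MetabolicModel, rows) -> None:
    for rid, name, equation, lb, ub, subsystem, pseudo in rows:
        stoich, _ = parse_equation(equation)
        for met_id in stoich:
            if not model.has_metabolite(met_id):
                model.add_metabolite(make_metabolite(met_id))
        model.add_reaction(Reaction(
            id=rid, name=name, stoichiometry=stoich,
            lower_bound=lb, upper_bound=ub, subsystem=subsystem,
            is_exchange=rid.startswith("EX_"), pseudo=pseudo))


def generate_core_network(spec: CoreNetworkSpec | None = None) -> MetabolicModel:
    """Build the core phototrophic network for a given spec (deterministic)."""
    spec = spec or CoreNetworkSpec()
    model = MetabolicModel("corenet")
    _add_rows(model, _base_reactions(spec))
    for ext in spec.extensions:
        _add_rows(model, _EXTENSION_TABLES[ext])
    model.annotations["generator"] = "cyanoflux.corenet"
    model.annotations["extensions"] = ",".join(spec.extensions)
    if spec.include_toy_biomass:
        toy_biomass_objective(model, inplace=True)
    model.validate()
    return model


def toy_biomass_objective(model: MetabolicModel,
                          inplace: bool = False) -> MetabolicModel:
    """Add the toy biomass drain and set it as the model objective.

    The biomass pseudo-reaction drains CBB triose, acetyl-CoA and glutamate in
    fixed proportions plus growth-associated ATP hydrolysis.  Applying it twice
    is an error.
    """
    if model.has_reaction("BIOMASS"):
        raise StructuralError("model already carries a biomass objective")
    out = model if inplace else model.copy()
    stoich, _ = parse_equation(BIOMASS_EQUATION)
    for met_id in stoich:
        if not out.has_metabolite(met_id):
            out.add_metabolite(make_metabolite(met_id))
    out.add_reaction(Reaction(
        id="BIOMASS", name="toy biomass drain", stoichiometry=stoich,
        lower_bound=0.0, upper_bound=_INF, subsystem="biomass", pseudo=True))
    out.add_reaction(Reaction(
        id="DM_biomass", name="biomass sink", stoichiometry=parse_equation(
            "biomass_c =>")[0],
        lower_bound=0.0, upper_bound=_INF, subsystem="exchange",
        is_exchange=True, pseudo=True))
    out.objective = {"BIOMASS": 1.0}
    return out


#: reaction ids used by the yield-accounting conventions on the core network
CORE_ACCOUNTING_IDS = {
    "photon_exchange": "EX_photon",
    "atp_synthase": "ATPS",
    "fnr": "FNR",
    "ndh1": "NDH1",
    "psii": "PSII",
    "psi": "PSI",
    "rubisco_carboxylase": "RBC_carb",
    "rubisco_oxygenase": "RBC_oxy",
    "o2_exchange": "EX_o2",
    "co2_exchange": "EX_co2",
    "hco3_exchange": "EX_hco3",
    "maintenance": "MAINT",
    "respiration": "COX",
    "mehler": "MEHLER",
    "ros_psii": "ROSPSII",
    "ros_psi": "ROSPSI",
    "cef": "CEF",
    "biomass": "BIOMASS",
}
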