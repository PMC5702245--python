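"""Construction of the bundled reduced central-metabolism network.

The network follows the MitoCore modelling conventions for mitochondrial
bioenergetics:

* the proton motive force (PMF) is a pseudo-metabolite co-transported by every
  step that moves charge (weight 0.82, the membrane-potential share) or
  protons (weight 0.18, the pH-gradient share) across the inner membrane;
* respiratory complexes I, III and IV move PMF matrix->cytosol in proportion
  to the protons they pump (10 per NADH, 6 per ubiquinol in total), and the
  ATP synthase consumes 2.7 PMF per ATP;
* 0.001% of complex-I flux is diverted to superoxide, cleared at the expense
  of matrix NADPH;
* prosthetic FAD/FADH never appears as a free species: succinate
  dehydrogenase and the ETF-fed acyl-CoA oxidation reduce ubiquinone
  directly;
* proton-coupled carriers that must not pump in reverse are split into an
  irreversible forward reaction (carrying the proton + PMF) and an
  irreversible reverse reaction carrying neither.

Reaction identifiers reuse reference-database (VMH-style) names where the
reaction is unchanged and carry the suffix ``_MitoCore`` where the form here
departs from the database version.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .model_core import (
    BOUNDARY_EXCHANGE,
    CYTOSOLIC,
    DEFAULT_BOUND,
    METABOLIC,
    MITOCHONDRIAL,
    MITO_TRANSPORT,
    PSEUDO,
    Metabolite,
    ModelNetwork,
    ModelStructureError,
    Reaction,
)

__all__ = [
    "PMFParameters",
    "TransportCategory",
    "pmf_coefficient",
    "make_transport_step",
    "make_respiratory_chain",
    "make_pseudo_reactions",
    "build_reduced_model",
    "build_oxphos_micromodel",
    "ATP_OBJECTIVE",
    "PROTON_LEAK_ID",
    "ATP_SYNTHASE_ID",
    "ANT_ID",
    "ANT_REVERSE_ID",
    "PI_CARRIER_ID",
    "PI_CARRIER_REVERSE_ID",
    "FUMARASE_GENE",
]

ATP_OBJECTIVE = "OF_ATP_MitoCore"
PROTON_LEAK_ID = "HtmB_MitoCore"
ATP_SYNTHASE_ID = "ATPS4m_MitoCore"
COMPLEX_I_ID = "NADH2_u10m_MitoCore"
COMPLEX_II_ID = "SUCD1m"
COMPLEX_III_ID = "CYOR_u10m_MitoCore"
COMPLEX_IV_ID = "CYOOm2_MitoCore"
ANT_ID = "ATPtm_MitoCore"
ANT_REVERSE_ID = "ATPtm_R_MitoCore"
PI_CARRIER_ID = "PIt2m_MitoCore"
PI_CARRIER_REVERSE_ID = "PIt2m_R_MitoCore"
BETA_OX_ID = "FAOXC160_MitoCore"

#: fumarate hydratase: one gene encodes both compartmental isoforms
FUMARASE_GENE = "FH"
FUMARASE_ENSEMBL = "ENSG00000091483"


@dataclass(frozen=True)
class PMFParameters:
    """Bioenergetic constants of the PMF representation.

    ``delta_psi_fraction`` and ``delta_ph_fraction`` are the relative
    contributions of the membrane potential and the pH gradient to the total
    PMF (dimensionless, sum to 1).  ``protons_per_atp`` is the H+/ATP ratio of
    the mitochondrial ATP synthase.  ``ros_fraction`` is the fraction of
    complex-I flux diverted to superoxide (0.001% = 1e-5).  ``complex_split``
    assigns the per-complex share of proton pumping; only the totals per NADH
    and per ubiquinol influence ATP yields.
    """

    delta_psi_fraction: float = 0.82
    delta_ph_fraction: float = 0.18
    protons_per_atp: float = 2.7
    ros_fraction: float = 1e-5
    pmf_per_nadh: float = 10.0
    pmf_per_qh2: float = 6.0
    complex_split: Tuple[Tuple[str, float], ...] = (
        ("CI", 4.0),
        ("CIII", 2.0),
        ("CIV", 4.0),
    )

    def __post_init__(self) -> None:
        if abs(self.delta_psi_fraction + self.delta_ph_fraction - 1.0) > 1e-12:
            raise ValueError("delta_psi_fraction + delta_ph_fraction must equal 1")
        split = self.split
        if abs(split["CI"] + split["CIII"] + split["CIV"] - self.pmf_per_nadh) > 1e-12:
            raise ValueError("complex_split must sum to pmf_per_nadh over CI+CIII+CIV")
        if abs(split["CIII"] + split["CIV"] - self.pmf_per_qh2) > 1e-12:
            raise ValueError("complex_split must sum to pmf_per_qh2 over CIII+CIV")
        if not 0 <= self.ros_fraction < 1:
            raise ValueError("ros_fraction must lie in [0, 1)")

    @property
    def split(self) -> Dict[str, float]:
        return dict(self.complex_split)

    @property
    def atp_export_cost(self) -> float:
        """PMF per cytosolic ATP beyond the synthase: ANT + phosphate carrier."""
        return self.delta_psi_fraction + self.delta_ph_fraction


#: alternative pumping split, selectable via PMFParameters(complex_split=...)
ALTERNATIVE_COMPLEX_SPLIT = (("CI", 4.0), ("CIII", 4.0), ("CIV", 2.0))


class TransportCategory(enum.Enum):
    """Mechanistic class of an inner-membrane transport step."""

    CARRIER = "carrier"  # characterised transporter, exchange/proton coupling
    UNIPORT_UNKNOWN = "uniport_unknown"  # transporter unidentified: plain uniport
    DIFFUSION = "diffusion"  # reversible uniport (O2, CO2, H2O, NH3)
    FLIPPASE = "flippase"  # ATP-hydrolysis-coupled lipid insertion


def pmf_coefficient(
    net_charge_translocated: int,
    electroneutral_protons: int,
    params: Optional[PMFParameters] = None,
) -> float:
    """PMF stoichiometric coefficient of a transport step.

    ``net_charge_translocated`` is the net elementary charge moved into the
    matrix per transport cycle (protons included); ``electroneutral_protons``
    is the number of protons co-moved per cycle.  A fully vectorial proton
    (charge 1, proton 1) scores 0.82 + 0.18 = 1.0.
    """
    if electroneutral_protons < 0:
        raise ValueError("proton count per transport cycle cannot be negative")
    p = params or PMFParameters()
    return (
        p.delta_psi_fraction * abs(net_charge_translocated)
        + p.delta_ph_fraction * electroneutral_protons
    )


# ---------------------------------------------------------------------------
# metabolite inventory
# ---------------------------------------------------------------------------

# (base id, name, charge, formula); compartment suffixes added on instantiation
_CYTOSOL_ONLY = [
    ("glc_D", "D-glucose", 0, "C6H12O6"),
    ("g6p", "D-glucose 6-phosphate", -2, "C6H11O9P"),
    ("f6p", "D-fructose 6-phosphate", -2, "C6H11O9P"),
    ("fdp", "D-fructose 1,6-bisphosphate", -4, "C6H10O12P2"),
    ("dhap", "dihydroxyacetone phosphate", -2, "C3H5O6P"),
    ("g3p", "glyceraldehyde 3-phosphate", -2, "C3H5O6P"),
    ("13dpg", "3-phospho-D-glyceroyl phosphate", -4, "C3H4O10P2"),
    ("3pg", "3-phospho-D-glycerate", -3, "C3H4O7P"),
    ("2pg", "2-phospho-D-glycerate", -3, "C3H4O7P"),
    ("pep", "phosphoenolpyruvate", -3, "C3H2O6P"),
    ("lac_L", "L-lactate", -1, "C3H5O3"),
    ("amp", "AMP", -2, "C10H12N5O7P"),
    ("ppi", "diphosphate", -3, "HO7P2"),
    ("hdca", "hexadecanoate (palmitate)", -1, "C16H31O2"),
    ("oaa", "oxaloacetate", -2, "C4H2O5"),
]

_BOTH_COMPARTMENTS = [
    ("pyr", "pyruvate", -1, "C3H3O3"),
    ("atp", "ATP", -4, "C10H12N5O13P3"),
    ("adp", "ADP", -3, "C10H12N5O10P2"),
    ("pi", "phosphate", -2, "HO4P"),
    ("h", "proton", 1, "H"),
    ("h2o", "water", 0, "H2O"),
    ("o2", "dioxygen", 0, "O2"),
    ("co2", "carbon dioxide", 0, "CO2"),
    ("nh3", "ammonia", 0, "H3N"),
    ("nad", "NAD+", -1, "C21H26N7O14P2"),
    ("nadh", "NADH", -2, "C21H27N7O14P2"),
    ("glu_L", "L-glutamate", -1, "C5H8NO4"),
    ("asp_L", "L-aspartate", -1, "C4H6NO4"),
    ("ala_L", "L-alanine", 0, "C3H7NO2"),
    ("gln_L", "L-glutamine", 0, "C5H10N2O3"),
    ("akg", "2-oxoglutarate", -2, "C5H4O5"),
    ("mal_L", "L-malate", -2, "C4H4O5"),
    ("fum", "fumarate", -2, "C4H2O4"),
    ("coa", "coenzyme A", -4, "C21H32N7O16P3S"),
    ("pmtcoa", "palmitoyl-CoA", -4, "C37H62N7O17P3S"),
    ("crn", "L-carnitine", 0, "C7H15NO3"),
    ("pmtcrn", "palmitoyl-L-carnitine", 0, "C23H45NO4"),
    ("bhb", "(R)-3-hydroxybutanoate", -1, "C4H7O3"),
    ("acac", "acetoacetate", -1, "C4H5O3"),
]

_MATRIX_ONLY = [
    ("oaa_mito", "oxaloacetate", -2, "C4H2O5"),  # handled specially below
    ("nadp", "NADP+", -3, "C21H25N7O17P3"),
    ("nadph", "NADPH", -4, "C21H26N7O17P3"),
    ("cit", "citrate", -3, "C6H5O7"),
    ("icit", "isocitrate", -3, "C6H5O7"),
    ("succ", "succinate", -2, "C4H4O4"),
    ("succoa", "succinyl-CoA", -5, "C25H35N7O19P3S"),
    ("accoa", "acetyl-CoA", -4, "C23H34N7O17P3S"),
    ("aacoa", "acetoacetyl-CoA", -4, "C25H36N7O18P3S"),
    ("q10", "ubiquinone-10", 0, "C59H90O4"),
    ("q10h2", "ubiquinol-10", 0, "C59H92O4"),
    ("ficytC", "ferricytochrome c", 3, None),
    ("focytC", "ferrocytochrome c", 2, None),
    ("o2s", "superoxide anion", -1, "O2"),
    ("h2o2", "hydrogen peroxide", 0, "H2O2"),
]


def _metabolites() -> List[Metabolite]:
    mets: List[Metabolite] = []
    for base, name, charge, formula in _CYTOSOL_ONLY:
        mets.append(Metabolite(base + "_c", name, CYTOSOLIC, charge, formula))
    for base, name, charge, formula in _BOTH_COMPARTMENTS:
        mets.append(Metabolite(base + "_c", name, CYTOSOLIC, charge, formula))
        mets.append(Metabolite(base + "_m", name, MITOCHONDRIAL, charge, formula))
    for base, name, charge, formula in _MATRIX_ONLY:
        if base == "oaa_mito":
            mets.append(Metabolite("oaa_m", name, MITOCHONDRIAL, charge, formula))
            continue
        mets.append(Metabolite(base + "_m", name, MITOCHONDRIAL, charge, formula))
    mets.append(Metabolite("pmf_c", "proton motive force", CYTOSOLIC, 0, None, True))
    mets.append(
        Metabolite("pmf_m", "proton motive force", MITOCHONDRIAL, 0, None, True)
    )
    return mets


# ---------------------------------------------------------------------------
# reaction constructors
# ---------------------------------------------------------------------------


def _rxn(
    rid: str,
    stoich: Dict[str, float],
    lb: float,
    ub: float = DEFAULT_BOUND,
    genes: Sequence[Tuple[str, str]] = (),
    subsystem: str = "",
    category: str = METABOLIC,
    **annotation: str,
) -> Reaction:
    return Reaction(
        id=rid,
        stoichiometry=dict(stoich),
        lower_bound=lb,
        upper_bound=ub,
        genes=list(genes),
        subsystem=subsystem,
        category=category,
        annotation=dict(annotation),
    )


def make_transport_step(
    rid: str,
    category: TransportCategory,
    imported: Sequence[str] = (),
    exported: Sequence[str] = (),
    proton_coupled: Optional[str] = None,
    net_charge: Optional[int] = None,
    metabolites: Optional[Dict[str, Metabolite]] = None,
    params: Optional[PMFParameters] = None,
    split_reverse: bool = False,
    genes: Sequence[Tuple[str, str]] = (),
    subsystem: str = "transport",
    **annotation: str,
) -> List[Reaction]:
    """Build an inner-membrane transport step with its PMF coefficient.

    ``imported``/``exported`` are base metabolite ids (no compartment suffix)
    moving into/out of the matrix.  ``proton_coupled`` is ``"in"`` for a
    symported proton moving inward, else None.  ``net_charge`` overrides the
    species-charge derivation when the carried species differs from the model
    species (e.g. the phosphate carrier moves monovalent phosphate and is
    electroneutral).  With ``split_reverse`` the step becomes an irreversible
    forward/reverse pair, the reverse carrying neither proton nor PMF so the
    pair can never pump PMF outward.
    """
    params = params or PMFParameters()
    mets = metabolites if metabolites is not None else {
        m.id: m for m in _metabolites()
    }
    protons = 1 if proton_coupled == "in" else 0
    if proton_coupled not in (None, "in"):
        raise ValueError("proton_coupled must be 'in' or None")

    def charge(base: str) -> int:
        return mets[base + "_c"].charge

    if net_charge is None:
        net_charge = (
            sum(charge(b) for b in imported)
            - sum(charge(b) for b in exported)
            + protons
        )
    if category is TransportCategory.DIFFUSION:
        if protons or net_charge:
            raise ModelStructureError(
                f"{rid}: a diffusion step cannot be charged or proton-coupled"
            )
        coeff = 0.0
    else:
        coeff = pmf_coefficient(net_charge, protons, params)

    stoich: Dict[str, float] = {}

    def add(met_id: str, value: float) -> None:
        stoich[met_id] = stoich.get(met_id, 0.0) + value
        if stoich[met_id] == 0.0:
            del stoich[met_id]

    for base in imported:
        add(base + "_c", -1.0)
        add(base + "_m", +1.0)
    for base in exported:
        add(base + "_m", -1.0)
        add(base + "_c", +1.0)
    if protons:
        add("h_c", -1.0)
        add("h_m", +1.0)
    if category is TransportCategory.FLIPPASE:
        # lipid insertion is ATP-hydrolysis coupled on the cytosolic face
        add("atp_c", -1.0)
        add("h2o_c", -1.0)
        add("adp_c", +1.0)
        add("pi_c", +1.0)
        add("h_c", +1.0)
    if coeff:
        add("pmf_c", -coeff)
        add("pmf_m", +coeff)

    if category is TransportCategory.FLIPPASE and stoich.get("atp_c", 0.0) >= 0:
        raise ModelStructureError(f"{rid}: a flippase must hydrolyse ATP")

    reversible = category is TransportCategory.DIFFUSION
    annotation = dict(annotation)
    annotation.setdefault("transport_category", category.value)
    forward = _rxn(
        rid,
        stoich,
        -DEFAULT_BOUND if reversible else 0.0,
        DEFAULT_BOUND,
        genes=genes,
        subsystem=subsystem,
        category=MITO_TRANSPORT,
        **annotation,
    )
    if not split_reverse:
        return [forward]

    rev: Dict[str, float] = {}
    for base in imported:
        rev[base + "_m"] = rev.get(base + "_m", 0.0) - 1.0
        rev[base + "_c"] = rev.get(base + "_c", 0.0) + 1.0
    for base in exported:
        rev[base + "_c"] = rev.get(base + "_c", 0.0) - 1.0
        rev[base + "_m"] = rev.get(base + "_m", 0.0) + 1.0
    reverse = _rxn(
        rid.replace("_MitoCore", "") + "_R_MitoCore",
        rev,
        0.0,
        DEFAULT_BOUND,
        genes=genes,
        subsystem=subsystem,
        category=MITO_TRANSPORT,
        transport_category=category.value,
        directionality_evidence="reverse leg of a split carrier; carries no "
        "proton or PMF so the pair cannot pump the gradient",
    )
    return [forward, reverse]


def make_respiratory_chain(params: Optional[PMFParameters] = None) -> Dict[str, Reaction]:
    """Respiratory chain with PMF pumping, ROS branch and direct Q coupling.

    Returns the complexes I-IV, the ATP synthase, the ETF-fed (ubiquinone
    coupled) beta-oxidation step standing in for ETF:QO, and the
    superoxide-removal chain.  No free FAD/FADH species exists anywhere:
    complex II and the acyl-CoA dehydrogenation reduce ubiquinone directly.
    """
    p = params or PMFParameters()
    f = p.ros_fraction
    split = p.split
    s1, s3, s4 = split["CI"], split["CIII"], split["CIV"]

    # vectorial protons are carried by the PMF species alone; the h terms of
    # the chain are the scalar (matrix-side) chemistry of each reaction
    complex_i = _rxn(
        COMPLEX_I_ID,
        {
            "nadh_m": -1.0,
            "h_m": -(1 - 2 * f),
            "q10_m": -(1 - f),
            "o2_m": -2 * f,
            "pmf_m": -s1 * (1 - f),
            "nad_m": 1.0,
            "q10h2_m": (1 - f),
            "o2s_m": 2 * f,
            "pmf_c": s1 * (1 - f),
        },
        0.0,
        genes=[("NDUFS1", ""), ("MT-ND1", "")],
        subsystem="oxphos",
        category=MITO_TRANSPORT,
        directionality_evidence="irreversible; 0.001% of flux diverted to "
        "superoxide with correspondingly reduced pumping",
    )
    complex_ii = _rxn(
        COMPLEX_II_ID,
        {"succ_m": -1.0, "q10_m": -1.0, "fum_m": 1.0, "q10h2_m": 1.0},
        0.0,
        genes=[("SDHA", ""), ("SDHB", "")],
        subsystem="oxphos",
        directionality_evidence="prosthetic FAD removed; reduces ubiquinone "
        "directly, no proton pumping",
    )
    etf_qo = _rxn(
        BETA_OX_ID,
        {
            "pmtcoa_m": -1.0,
            "coa_m": -7.0,
            "q10_m": -7.0,
            "h2o_m": -7.0,
            "nad_m": -7.0,
            "accoa_m": 8.0,
            "q10h2_m": 7.0,
            "nadh_m": 7.0,
            "h_m": 7.0,
        },
        0.0,
        genes=[("ACADVL", ""), ("HADHA", ""), ("HADHB", "")],
        subsystem="beta_oxidation",
        directionality_evidence="lumped beta-oxidation of palmitoyl-CoA; "
        "ETF/ETF:QO electrons passed directly to ubiquinone (no free FAD)",
    )
    complex_iii = _rxn(
        COMPLEX_III_ID,
        {
            "q10h2_m": -1.0,
            "ficytC_m": -2.0,
            "pmf_m": -s3,
            "q10_m": 1.0,
            "focytC_m": 2.0,
            "h_m": 2.0,
            "pmf_c": s3,
        },
        0.0,
        genes=[("UQCRC1", ""), ("CYC1", "")],
        subsystem="oxphos",
        category=MITO_TRANSPORT,
    )
    complex_iv = _rxn(
        COMPLEX_IV_ID,
        {
            # written per O2, i.e. two electron pairs -> 2*s4 PMF
            "focytC_m": -4.0,
            "o2_m": -1.0,
            "h_m": -4.0,
            "pmf_m": -2.0 * s4,
            "ficytC_m": 4.0,
            "h2o_m": 2.0,
            "pmf_c": 2.0 * s4,
        },
        0.0,
        genes=[("COX4I1", ""), ("MT-CO1", "")],
        subsystem="oxphos",
        category=MITO_TRANSPORT,
    )
    n = p.protons_per_atp
    atp_synthase = _rxn(
        ATP_SYNTHASE_ID,
        {
            "adp_m": -1.0,
            "pi_m": -1.0,
            "h_m": -1.0,
            "pmf_c": -n,
            "atp_m": 1.0,
            "h2o_m": 1.0,
            "pmf_m": n,
        },
        -DEFAULT_BOUND,
        genes=[("ATP5F1A", ""), ("ATP5F1B", "")],
        subsystem="oxphos",
        category=MITO_TRANSPORT,
        directionality_evidence=f"reversible; {n} H+ (and PMF) per ATP",
    )
    sod = _rxn(
        "SPODMm",
        {"o2s_m": -2.0, "h_m": -2.0, "h2o2_m": 1.0, "o2_m": 1.0},
        0.0,
        genes=[("SOD2", "")],
        subsystem="ros_detox",
    )
    peroxidase = _rxn(
        "GTHPm_MitoCore",
        {"h2o2_m": -1.0, "nadph_m": -1.0, "h_m": -1.0, "h2o_m": 2.0, "nadp_m": 1.0},
        0.0,
        genes=[("GPX1", ""), ("GSR", "")],
        subsystem="ros_detox",
        directionality_evidence="lumped glutathione peroxidase/reductase: "
        "peroxide cleared at the expense of matrix NADPH",
    )
    for rxn in (complex_i, complex_ii, etf_qo, complex_iii, complex_iv):
        for met in rxn.stoichiometry:
            if met.startswith(("fad", "fadh")):
                raise ModelStructureError(
                    f"{rxn.id}: free FAD/FADH species are not allowed"
                )
    return {
        "complex_i": complex_i,
        "complex_ii": complex_ii,
        "etf_qo": etf_qo,
        "complex_iii": complex_iii,
        "complex_iv": complex_iv,
        "atp_synthase": atp_synthase,
        "superoxide_dismutase": sod,
        "peroxide_clearance": peroxidase,
    }


def make_pseudo_reactions() -> List[Reaction]:
    """The four pseudo reactions usable as FBA objectives.

    ATP hydrolysis summarises cellular ATP demand; the other three drain
    biosynthetic precursors for heme, membrane lipid and amino-acid supply.
    All are balance-exempt summaries, not chemistry.
    """
    return [
        _rxn(
            ATP_OBJECTIVE,
            {"atp_c": -1.0, "h2o_c": -1.0, "adp_c": 1.0, "pi_c": 1.0, "h_c": 1.0},
            0.0,
            subsystem="pseudo",
            category=PSEUDO,
            directionality_evidence="cellular ATP demand; default objective",
        ),
        _rxn(
            "OF_HEME_MitoCore",
            {"succoa_m": -1.0, "coa_m": 1.0},
            0.0,
            subsystem="pseudo",
            category=PSEUDO,
            directionality_evidence="heme biosynthesis precursor drain "
            "(succinyl-CoA)",
        ),
        _rxn(
            "OF_LIPID_MitoCore",
            {"pmtcoa_c": -1.0, "pi_c": -0.5, "coa_c": 1.0},
            0.0,
            subsystem="pseudo",
            category=PSEUDO,
            directionality_evidence="membrane phospholipid biosynthesis drain "
            "(palmitoyl-CoA + headgroup phosphate)",
        ),
        _rxn(
            "OF_AA_MitoCore",
            {"ala_L_c": -1.0, "glu_L_c": -1.0, "asp_L_c": -1.0, "gln_L_c": -1.0},
            0.0,
            subsystem="pseudo",
            category=PSEUDO,
            directionality_evidence="amino-acid biosynthesis demand drain",
        ),
    ]


def _exchange(met_base: str, lb: float, ub: float = DEFAULT_BOUND) -> Reaction:
    return _rxn(
        f"EX_{met_base}",
        {met_base + "_c": -1.0},
        lb,
        ub,
        subsystem="exchange",
        category=BOUNDARY_EXCHANGE,
        directionality_evidence="cytosol boundary step; negative flux = uptake",
    )


# ---------------------------------------------------------------------------
# the bundled reduced network
# ---------------------------------------------------------------------------


def _core_reactions(params: PMFParameters) -> List[Reaction]:
    """All metabolic (non-transport, non-exchange) reactions."""
    r: List[Reaction] = []
    gly = "glycolysis"
    r += [
        _rxn("HEX1", {"glc_D_c": -1, "atp_c": -1, "g6p_c": 1, "adp_c": 1, "h_c": 1},
             0, genes=[("HK1", "")], subsystem=gly),
        _rxn("PGI", {"g6p_c": -1, "f6p_c": 1}, -DEFAULT_BOUND,
             genes=[("GPI", "")], subsystem=gly),
        _rxn("PFK", {"f6p_c": -1, "atp_c": -1, "fdp_c": 1, "adp_c": 1, "h_c": 1},
             0, genes=[("PFKM", "")], subsystem=gly),
        _rxn("FBA", {"fdp_c": -1, "dhap_c": 1, "g3p_c": 1}, -DEFAULT_BOUND,
             genes=[("ALDOA", "")], subsystem=gly),
        _rxn("TPI", {"dhap_c": -1, "g3p_c": 1}, -DEFAULT_BOUND,
             genes=[("TPI1", "")], subsystem=gly),
        _rxn("GAPD", {"g3p_c": -1, "nad_c": -1, "pi_c": -1,
                      "13dpg_c": 1, "nadh_c": 1, "h_c": 1}, -DEFAULT_BOUND,
             genes=[("GAPDH", "")], subsystem=gly),
        _rxn("PGK", {"13dpg_c": -1, "adp_c": -1, "3pg_c": 1, "atp_c": 1},
             -DEFAULT_BOUND, genes=[("PGK1", "")], subsystem=gly),
        _rxn("PGM", {"3pg_c": -1, "2pg_c": 1}, -DEFAULT_BOUND,
             genes=[("PGAM1", "")], subsystem=gly),
        _rxn("ENO", {"2pg_c": -1, "pep_c": 1, "h2o_c": 1}, -DEFAULT_BOUND,
             genes=[("ENO1", "")], subsystem=gly),
        _rxn("PYK", {"pep_c": -1, "adp_c": -1, "h_c": -1, "pyr_c": 1, "atp_c": 1},
             0, genes=[("PKM", "")], subsystem=gly),
        _rxn("LDH_L", {"lac_L_c": -1, "nad_c": -1, "pyr_c": 1, "nadh_c": 1, "h_c": 1},
             -DEFAULT_BOUND, genes=[("LDHA", "")], subsystem="lactate_oxidation"),
    ]
    ana = "anaplerosis"
    r += [
        _rxn("PEPCK", {"oaa_c": -1, "atp_c": -1, "pep_c": 1, "co2_c": 1, "adp_c": 1},
             0, genes=[("PCK1", "")], subsystem=ana,
             directionality_evidence="irreversible toward PEP; GTP modelled as ATP"),
        _rxn("PCm", {"pyr_m": -1, "co2_m": -1, "atp_m": -1, "h2o_m": -1,
                     "oaa_m": 1, "adp_m": 1, "pi_m": 1, "h_m": 2},
             0, genes=[("PC", "")], subsystem=ana),
        _rxn("ME2m", {"mal_L_m": -1, "nad_m": -1, "pyr_m": 1, "co2_m": 1, "nadh_m": 1},
             0, genes=[("ME2", "")], subsystem=ana,
             directionality_evidence="NAD-dependent malic enzyme; 4-carbon exit "
             "route to pyruvate"),
        _rxn("ADK1", {"atp_c": -1, "amp_c": -1, "adp_c": 2}, -DEFAULT_BOUND,
             genes=[("AK1", "")], subsystem=ana),
        _rxn("PPA", {"ppi_c": -1, "h2o_c": -1, "pi_c": 2, "h_c": 1}, 0,
             genes=[("PPA1", "")], subsystem=ana),
    ]
    tca = "tca_cycle"
    r += [
        _rxn("PDHm", {"pyr_m": -1, "coa_m": -1, "nad_m": -1,
                      "accoa_m": 1, "co2_m": 1, "nadh_m": 1}, 0,
             genes=[("PDHA1", ""), ("DLAT", "")], subsystem=tca,
             directionality_evidence="complex modelled as one reaction"),
        _rxn("CSm", {"accoa_m": -1, "oaa_m": -1, "h2o_m": -1,
                     "cit_m": 1, "coa_m": 1, "h_m": 1}, 0,
             genes=[("CS", "")], subsystem=tca),
        _rxn("ACONTm", {"cit_m": -1, "icit_m": 1}, -DEFAULT_BOUND,
             genes=[("ACO2", "")], subsystem=tca),
        _rxn("ICDHxm", {"icit_m": -1, "nad_m": -1, "akg_m": 1, "co2_m": 1,
                        "nadh_m": 1}, 0,
             genes=[("IDH3A", "")], subsystem=tca),
        _rxn("ICDHym", {"icit_m": -1, "nadp_m": -1, "akg_m": 1, "co2_m": 1,
                        "nadph_m": 1}, 0,
             genes=[("IDH2", "")], subsystem=tca,
             directionality_evidence="irreversible forward to keep NADH and "
             "NADPH pools separate"),
        _rxn("AKGDm", {"akg_m": -1, "coa_m": -1, "nad_m": -1,
                       "succoa_m": 1, "co2_m": 1, "nadh_m": 1}, 0,
             genes=[("OGDH", ""), ("DLST", "")], subsystem=tca),
        _rxn("SUCOASm", {"succoa_m": -1, "adp_m": -1, "pi_m": -1,
                         "succ_m": 1, "coa_m": 1, "atp_m": 1}, -DEFAULT_BOUND,
             genes=[("SUCLA2", "")], subsystem=tca,
             directionality_evidence="GTP modelled as ATP"),
        _rxn("FUMm", {"fum_m": -1, "h2o_m": -1, "mal_L_m": 1}, -DEFAULT_BOUND,
             genes=[(FUMARASE_GENE, FUMARASE_ENSEMBL)], subsystem=tca),
        _rxn("MDHm", {"mal_L_m": -1, "nad_m": -1, "oaa_m": 1, "nadh_m": 1, "h_m": 1},
             -DEFAULT_BOUND, genes=[("MDH2", "")], subsystem=tca),
    ]
    mas = "malate_aspartate_shuttle"
    r += [
        _rxn("FUM", {"fum_c": -1, "h2o_c": -1, "mal_L_c": 1}, -DEFAULT_BOUND,
             genes=[(FUMARASE_GENE, FUMARASE_ENSEMBL)], subsystem=tca,
             directionality_evidence="cytosolic isoform; same gene as FUMm"),
        _rxn("MDH", {"mal_L_c": -1, "nad_c": -1, "oaa_c": 1, "nadh_c": 1, "h_c": 1},
             -DEFAULT_BOUND, genes=[("MDH1", "")], subsystem=mas),
        _rxn("ASPTA", {"asp_L_c": -1, "akg_c": -1, "oaa_c": 1, "glu_L_c": 1},
             -DEFAULT_BOUND, genes=[("GOT1", "")], subsystem=mas),
        _rxn("ASPTAm", {"asp_L_m": -1, "akg_m": -1, "oaa_m": 1, "glu_L_m": 1},
             -DEFAULT_BOUND, genes=[("GOT2", "")], subsystem=mas),
    ]
    aa = "amino_acid_degradation"
    r += [
        _rxn("ALATA_Lm", {"ala_L_m": -1, "akg_m": -1, "pyr_m": 1, "glu_L_m": 1},
             0, genes=[("GPT2", "")], subsystem=aa),
        _rxn("GLUDm", {"glu_L_m": -1, "h2o_m": -1, "nad_m": -1,
                       "akg_m": 1, "nh3_m": 1, "nadh_m": 1, "h_m": 2},
             -DEFAULT_BOUND, genes=[("GLUD1", "")], subsystem=aa,
             directionality_evidence="nitrogen disposal to free ammonia, which "
             "is effluxed; no urea cycle in the reduced network"),
        _rxn("GLUNm", {"gln_L_m": -1, "h2o_m": -1, "glu_L_m": 1, "nh3_m": 1,
                       "h_m": 1}, 0,
             genes=[("GLS", "")], subsystem=aa),
    ]
    ket = "ketone_degradation"
    r += [
        _rxn("BDHm", {"bhb_m": -1, "nad_m": -1, "acac_m": 1, "nadh_m": 1, "h_m": 1},
             -DEFAULT_BOUND, genes=[("BDH1", "")], subsystem=ket),
        _rxn("OCOAT1m", {"acac_m": -1, "succoa_m": -1, "aacoa_m": 1, "succ_m": 1},
             0, genes=[("OXCT1", "")], subsystem=ket),
        _rxn("ACACT1rm", {"aacoa_m": -1, "coa_m": -1, "accoa_m": 2}, 0,
             genes=[("ACAT1", "")], subsystem=ket),
    ]
    fat = "fatty_acid_activation"
    r += [
        _rxn("FACOAL160", {"hdca_c": -1, "atp_c": -1, "coa_c": -1,
                           "pmtcoa_c": 1, "amp_c": 1, "ppi_c": 1}, 0,
             genes=[("ACSL1", "")], subsystem=fat),
        _rxn("CPT1", {"pmtcoa_c": -1, "crn_c": -1, "pmtcrn_c": 1, "coa_c": 1}, 0,
             genes=[("CPT1B", "")], subsystem="carnitine_shuttle"),
        _rxn("CPT2", {"pmtcrn_m": -1, "coa_m": -1, "pmtcoa_m": 1, "crn_m": 1}, 0,
             genes=[("CPT2", "")], subsystem="carnitine_shuttle"),
    ]
    return r


def _transport_reactions(
    mets: Dict[str, Metabolite], params: PMFParameters
) -> List[Reaction]:
    T = TransportCategory
    r: List[Reaction] = []
    # ANT: ATP4-/ADP3- counter-exchange, electrogenic (Eq.-1 form), split pair
    r += make_transport_step(
        ANT_ID, T.CARRIER, imported=["adp"], exported=["atp"],
        metabolites=mets, params=params, split_reverse=True,
        genes=[("SLC25A4", "")],
        directionality_evidence="electrogenic counter-exchange: +1 charge "
        "inward, 0.82 PMF co-transported",
    )
    # phosphate carrier: monovalent Pi/H+ symport, electroneutral (Eq.-2 form)
    r += make_transport_step(
        PI_CARRIER_ID, T.CARRIER, imported=["pi"], proton_coupled="in",
        net_charge=0, metabolites=mets, params=params, split_reverse=True,
        genes=[("SLC25A3", "")],
        directionality_evidence="electroneutral H2PO4-/H+ symport, 0.18 PMF",
    )
    r += make_transport_step(
        "PYRt2m_MitoCore", T.CARRIER, imported=["pyr"], proton_coupled="in",
        net_charge=0, metabolites=mets, params=params,
        genes=[("MPC1", ""), ("MPC2", "")],
    )
    r += make_transport_step(
        "GLUt2m_MitoCore", T.CARRIER, imported=["glu_L"], proton_coupled="in",
        net_charge=0, metabolites=mets, params=params,
        genes=[("SLC25A22", "")],
    )
    # aspartate/glutamate carrier: electrogenic + proton-coupled, 1.0 PMF
    r += make_transport_step(
        "ASPGLUm_MitoCore", T.CARRIER, imported=["glu_L"], exported=["asp_L"],
        proton_coupled="in", metabolites=mets, params=params,
        genes=[("SLC25A12", "")],
        directionality_evidence="aspartate efflux leg of the malate-aspartate "
        "shuttle; irreversible so it cannot pump PMF",
    )
    # oxoglutarate and dicarboxylate carriers: electroneutral exchanges
    ogc = _rxn("AKGMALtm", {"akg_m": -1, "mal_L_c": -1, "akg_c": 1, "mal_L_m": 1},
               -DEFAULT_BOUND, genes=[("SLC25A11", "")], subsystem="transport",
               category=MITO_TRANSPORT, transport_category=T.CARRIER.value,
               directionality_evidence="electroneutral 2-:2- exchange, 0 PMF")
    dic = _rxn("MALPItm", {"mal_L_m": -1, "pi_c": -1, "mal_L_c": 1, "pi_m": 1},
               -DEFAULT_BOUND, genes=[("SLC25A10", "")], subsystem="transport",
               category=MITO_TRANSPORT, transport_category=T.CARRIER.value,
               directionality_evidence="electroneutral 2-:2- exchange, 0 PMF")
    fumt = _rxn("FUMPItm_MitoCore", {"fum_m": -1, "pi_c": -1, "fum_c": 1, "pi_m": 1},
                0, genes=[("SLC25A10", "")], subsystem="transport",
                category=MITO_TRANSPORT, transport_category=T.CARRIER.value,
                directionality_evidence="fumarate efflux against phosphate; "
                "electroneutral")
    cact = _rxn("CARN160t_MitoCore",
                {"pmtcrn_c": -1, "crn_m": -1, "pmtcrn_m": 1, "crn_c": 1},
                -DEFAULT_BOUND, genes=[("SLC25A20", "")],
                subsystem="carnitine_shuttle", category=MITO_TRANSPORT,
                transport_category=T.CARRIER.value,
                directionality_evidence="electroneutral acylcarnitine/carnitine "
                "exchange")
    r += [ogc, dic, fumt, cact]
    r += make_transport_step(
        "BHBtm_MitoCore", T.CARRIER, imported=["bhb"], proton_coupled="in",
        net_charge=0, metabolites=mets, params=params,
        directionality_evidence="monocarboxylate/H+ symport, electroneutral",
    )
    r += make_transport_step(
        "ACACtm_MitoCore", T.CARRIER, imported=["acac"], proton_coupled="in",
        net_charge=0, metabolites=mets, params=params,
        directionality_evidence="monocarboxylate/H+ symport, electroneutral",
    )
    # neutral amino acids: transporter unidentified -> plain uniport, 0 PMF
    for rid, base in (("ALAtm", "ala_L"), ("GLNtm", "gln_L")):
        rxn = _rxn(rid, {base + "_c": -1, base + "_m": 1}, -DEFAULT_BOUND,
                   subsystem="transport", category=MITO_TRANSPORT,
                   transport_category=T.UNIPORT_UNKNOWN.value,
                   directionality_evidence="uncharged; uniport, no PMF")
        r.append(rxn)
    for rid, base in (("O2tm", "o2"), ("CO2tm", "co2"), ("H2Otm", "h2o"),
                      ("NH3tm", "nh3")):
        r += make_transport_step(
            rid, T.DIFFUSION, imported=[base], metabolites=mets, params=params,
        )
    # scalar-proton equilibration: every energetic consequence of proton
    # movement is carried by the PMF species, so the h pools themselves
    # equilibrate freely; without this valve the scalar ledger of the matrix
    # would overdetermine (and silently distort) the PMF bookkeeping
    r.append(
        _rxn("HtmA_MitoCore", {"h_c": -1.0, "h_m": 1.0}, -DEFAULT_BOUND,
             subsystem="transport", category=MITO_TRANSPORT,
             transport_category=T.DIFFUSION.value,
             directionality_evidence="scalar proton equilibration; carries no "
             "PMF (vectorial energetics live on the PMF species)")
    )
    # UCP2 proton leak: vectorial proton moving down the gradient into the
    # matrix; a forced lower bound models an imposed leak
    r += make_transport_step(
        PROTON_LEAK_ID, T.CARRIER, imported=[], proton_coupled="in",
        metabolites=mets, params=params, genes=[("UCP2", "")],
        directionality_evidence="uncoupling protein 2; dissipates one PMF per "
        "proton re-entering the matrix",
    )
    return r


_FUEL_EXCHANGES = (
    "glc_D", "hdca", "lac_L", "bhb", "acac", "ala_L", "glu_L", "asp_L", "gln_L",
)
_OPEN_EXCHANGES = ("co2", "h2o", "nh3", "h", "pi")


def build_reduced_model(
    params: Optional[PMFParameters] = None,
    qc: bool = True,
) -> ModelNetwork:
    """Assemble the bundled reduced two-compartment network.

    Covers glycolysis, pyruvate dehydrogenase, the TCA cycle, the
    malate-aspartate shuttle, the carnitine shuttle with beta-oxidation of
    hexadecanoate, ketone-body and lactate oxidation, degradation routes for
    alanine/aspartate/glutamate/glutamine, the full respiratory chain with
    ROS branch, boundary exchanges for all fuels plus O2/CO2/H2O/NH3/
    fumarate/Pi/H+, the four pseudo objective reactions and the UCP2 proton
    leak.  Fuel uptakes default to zero; oxygen and the inorganic exchanges
    are open.

    With ``qc=True`` (default) the build fails if the assembled network has
    blocked reactions, dead-end metabolites, balance problems or an
    energy-generating cycle.
    """
    params = params or PMFParameters()
    model = ModelNetwork(notes="bundled reduced central-metabolism network")
    mets = {m.id: m for m in _metabolites()}
    for met in mets.values():
        model.add_metabolite(met)
    for rxn in _core_reactions(params):
        model.add_reaction(rxn)
    for rxn in make_respiratory_chain(params).values():
        model.add_reaction(rxn)
    for rxn in _transport_reactions(mets, params):
        model.add_reaction(rxn)
    for rxn in make_pseudo_reactions():
        model.add_reaction(rxn)
    for base in _FUEL_EXCHANGES:
        model.add_reaction(_exchange(base, 0.0))
    model.add_reaction(_exchange("o2", 0.0))
    for base in _OPEN_EXCHANGES:
        model.add_reaction(_exchange(base, -DEFAULT_BOUND))
    model.add_reaction(
        _rxn("EX_fum", {"fum_c": -1.0}, 0.0, DEFAULT_BOUND,
             subsystem="exchange", category=BOUNDARY_EXCHANGE,
             directionality_evidence="fumarate efflux only (disease marker)")
    )
    model.objective_id = ATP_OBJECTIVE
    model.validate()
    if qc:
        from .model_qc import run_qc

        report = run_qc(model)
        if not report.passed:
            raise ModelStructureError(
                "built model fails quality control: "
                f"blocked={report.blocked_reactions} "
                f"dead_ends={report.dead_end_metabolites} "
                f"energy_cycle_atp={report.energy_cycle_atp} "
                f"balance={report.balance_issues}"
            )
    return model


def build_oxphos_micromodel(params: Optional[PMFParameters] = None) -> ModelNetwork:
    """Minimal oxidative-phosphorylation model for yield arithmetic.

    A matrix NADH source feeding complexes I/III/IV, the ATP synthase, the
    adenine-nucleotide and phosphate carriers and cytosolic ATP hydrolysis.
    With the NADH source capped at 1, the maximal ATP-hydrolysis flux equals
    pmf_per_nadh*(1-ros_fraction)/(protons_per_atp + 1): every exported ATP
    costs 2.7 PMF at the synthase plus 0.82 (ANT) + 0.18 (phosphate carrier).
    """
    params = params or PMFParameters()
    model = ModelNetwork(notes="oxphos micro-model")
    mets = {m.id: m for m in _metabolites()}
    chain = make_respiratory_chain(params)
    keep = [
        chain["complex_i"], chain["complex_iii"], chain["complex_iv"],
        chain["atp_synthase"],
    ]
    needed = set()
    for rxn in keep:
        needed |= set(rxn.stoichiometry)
    extra = [
        make_pseudo_reactions()[0],  # ATP hydrolysis objective
        _rxn("DH_SRC", {"nad_m": -1.0, "nadh_m": 1.0, "h_m": 1.0}, 0.0, 1.0,
             subsystem="pseudo", category=PSEUDO,
             directionality_evidence="matrix NADH source, capped at 1"),
        _rxn("O2S_SINK", {"o2s_m": -1.0, "h_m": -1.0}, 0.0, DEFAULT_BOUND,
             subsystem="pseudo", category=PSEUDO,
             directionality_evidence="superoxide drain (charge + proton)"),
    ]
    transports = make_transport_step(
        ANT_ID, TransportCategory.CARRIER, imported=["adp"], exported=["atp"],
        metabolites=mets, params=params,
    ) + make_transport_step(
        PI_CARRIER_ID, TransportCategory.CARRIER, imported=["pi"],
        proton_coupled="in", net_charge=0, metabolites=mets, params=params,
    ) + make_transport_step(
        "O2tm", TransportCategory.DIFFUSION, imported=["o2"],
        metabolites=mets, params=params,
    ) + make_transport_step(
        "H2Otm", TransportCategory.DIFFUSION, imported=["h2o"],
        metabolites=mets, params=params,
    )
    for rxn in extra + transports:
        needed |= set(rxn.stoichiometry)
    for met_id in sorted(needed):
        model.add_metabolite(mets[met_id])
    for rxn in keep + extra + transports:
        model.add_reaction(rxn)
    for base in ("o2", "h2o", "h"):
        model.add_reaction(_exchange(base, -DEFAULT_BOUND))
    model.objective_id = ATP_OBJECTIVE
    model.validate()
    return model
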