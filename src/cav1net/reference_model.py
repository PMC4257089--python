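"""Curated CD4+ T-cell logical model centered on CAV1 signaling.

A compact Boolean model of CAV1-dependent CD4+ T-cell signaling, built as a
faithful-in-named-interactions miniature: every internal edge encodes an
interaction with a documented qualitative direction (see the per-node
annotations and the shipped manifest TSV), and the wiring is constrained so
that the model reproduces the qualitative behaviors expected of it:

* CAV1 is a required (AND) term in the TCR-proximal branch (LCK/FYN/zeta
  phosphorylation), the integrin branch, and the KSR1 scaffold of the
  RAF/MEK/ERK cascade — knockout shuts these down;
* CAV1 restrains CD26, BCL10, RAC1, and GATA3 — knockout up-regulates them;
* the CD28 costimulatory branch (CD28 -> PI3K -> AKT) carries no CAV1
  dependency, so CD28 is insensitive to CAV1 genotype;
* input-output dose-response behavior is monotone for the validated pairs
  (APC->ERK, ECM->F_actin, GalphaQ_L->PI3K, ECM->MAPK, IL2->MAPK,
  Galpha12_13_L->Cdc42).

External inputs are the 29 tissue-environment stimuli plus the two GPCR
ligands used for dose-response sweeps and the CAV1 activator species that
artificially drives CAV1 independent of its upstream regulators.

The model is frozen: ``REFERENCE_MODEL_SHA256`` is the digest of the
canonical rule text, checked at test time against both the builder output
and the packaged data files.
"""

from __future__ import annotations

import hashlib
from importlib import resources
from typing import Dict, List, Tuple

from .network import LogicalNetwork, NodeSpec, format_rules, parse_rules_text
from .rules import And, Expr, Not, Or, Var

__all__ = [
    "build_reference_model",
    "reference_rules_text",
    "REFERENCE_MODEL_SHA256",
    "KO_DYSREGULATED",
    "KO_INVARIANT",
    "VALIDATED_PHENOMENA",
    "build_manifest",
]

#: proteins dysregulated by CAV1 knockout across all three tissue conditions
KO_DYSREGULATED = ("CD26", "CARMA1", "FYN", "SHC1", "SOS", "SHP2", "NOS2A",
                   "BCL10", "GRB2")

#: costimulatory protein expected to be insensitive to CAV1 genotype
KO_INVARIANT = "CD28"

#: validated input-output pairs (swept input, output readout)
VALIDATED_PHENOMENA = (
    ("APC", "ERK"),
    ("ECM", "F_actin"),
    ("GalphaQ_L", "PI3K"),
    ("ECM", "MAPK"),
    ("IL2", "MAPK"),
    ("Galpha12_13_L", "Cdc42"),
)

_RULES = """\
# Curated CD4+ T-cell CAV1 signaling model
input APC
input ECM
input CGC
input Alpha_13L
input GalphaS_L
input GP130
input IFNB
input IFNG
input IFNGR1
input IFNGR2
input IL10
input IL10RA
input IL10RB
input IL12
input IL15
input IL15RA
input IL18
input IL21
input IL22
input IL23
input IL27
input IL27RA
input IL2
input IL2RB
input IL4
input IL6
input IL6RA
input IL9
input TGFB
input GalphaQ_L
input Galpha12_13_L
input CAV1_Activator
TCR = APC
CD28 = APC & CGC
CAV1 = TCR | ECM | CAV1_Activator
LCK = TCR & CAV1
FYN = TCR & CAV1
TCRzeta = LCK | FYN
ZAP70 = TCRzeta
LAT = ZAP70
Integrin = ECM & CAV1
IL2R = IL2
IL10R = IL10 & IL10RA & IL10RB
IFNGR = IFNG & IFNGR1 & IFNGR2
IL6R = IL6 & IL6RA & GP130
IL27R = IL27 & IL27RA & GP130
IL15R = IL15 & IL15RA & IL2RB
SHC1 = Integrin | IL2R
GRB2 = SHC1 | LAT
SOS = GRB2
RAS = SOS
KSR1 = CAV1
RAF = RAS & KSR1
MEK = RAF
ERK = MEK
MAPK = ERK & (Integrin | IL2R)
CARMA1 = LCK
BCL10 = CARMA1 | !CAV1
MALT1 = CARMA1 & BCL10
NFKB = MALT1
CD26 = !CAV1
SHP2 = Integrin
NOS2A = NFKB & !IL10R
PI3K = CD28 | GalphaQ_L
AKT = PI3K
RAC1 = Integrin | !CAV1
Cdc42 = Galpha12_13_L | Alpha_13L
ARP2_3 = RAC1 | Cdc42
F_actin = ARP2_3 & Integrin
Th1_Signal = IFNGR | (IL12 & IL18) | IL27R | IFNB
GATA3 = !CAV1 & !Th1_Signal
Gamma_Chain = IL2R | IL15R | IL4 | IL9 | IL21
STAT3_Signal = IL6R | IL10R | IL21 | IL22 | IL23
Treg_Skew = TGFB & !Th1_Signal
cAMP_PKA = GalphaS_L
Survival = AKT | Gamma_Chain | STAT3_Signal
Proliferation = ERK & NFKB & !Treg_Skew & !cAMP_PKA
Cytoskeletal_Rearrangement = F_actin
"""

#: provenance note per internal node (mirrors the shipped manifest TSV)
ANNOTATIONS: Dict[str, str] = {
    "TCR": "TCR engagement by peptide-MHC on an antigen-presenting cell",
    "CD28": "CD28 costimulation by APC ligands; signals independently of CAV1",
    "CAV1": "membrane scaffold engaged by TCR and integrin/ECM contact; the "
            "activator species drives it independently of upstream regulators",
    "LCK": "CAV1-dependent p56lck activation at the immune synapse",
    "FYN": "CAV1-dependent Fyn activation at the immune synapse",
    "TCRzeta": "TCR-zeta chain phosphorylation by the Src kinases Lck/Fyn",
    "ZAP70": "ZAP70 recruitment to phosphorylated TCR-zeta",
    "LAT": "LAT adaptor phosphorylation by ZAP70",
    "Integrin": "integrin engagement of extracellular-matrix components, "
                "scaffolded by CAV1",
    "IL2R": "IL-2 receptor engagement",
    "IL10R": "IL-10 receptor complex (ligand plus R-alpha and R-beta chains)",
    "IFNGR": "IFN-gamma receptor complex (ligand plus R1 and R2 chains)",
    "IL6R": "IL-6 receptor complex; requires the gp130 co-receptor",
    "IL27R": "IL-27 receptor complex; requires the gp130 co-receptor",
    "IL15R": "IL-15 receptor complex; shares the IL-2R beta chain",
    "SHC1": "SHC adaptor recruited by integrin and IL-2R signaling",
    "GRB2": "GRB2 adaptor recruited via SHC1 or LAT",
    "SOS": "SOS exchange factor in the GRB2 complex",
    "RAS": "RAS activation by SOS",
    "KSR1": "KSR1 scaffold of the RAF/MEK/ERK cascade, organized by CAV1",
    "RAF": "RAF activation by RAS on the KSR1 scaffold",
    "MEK": "MEK activation by RAF",
    "ERK": "ERK activation by MEK",
    "MAPK": "MAPK-pathway readout: ERK output under sustained receptor "
            "engagement (integrin or IL-2R)",
    "CARMA1": "CARMA1 activation downstream of TCR-proximal kinase signaling",
    "BCL10": "BCL10, engaged by CARMA1 and restrained by CAV1 (up in knockout)",
    "MALT1": "MALT1 in the CARMA1-BCL10-MALT1 complex",
    "NFKB": "NF-kB activation by the CBM complex",
    "CD26": "CD26, sequestered by its interaction with CAV1 (up in knockout)",
    "SHP2": "SHP2 phosphatase recruited to integrin adhesion signaling",
    "NOS2A": "inducible NO synthase: NF-kB-driven, suppressed by IL-10",
    "PI3K": "PI3-kinase activation via CD28 costimulation or GalphaQ GPCR",
    "AKT": "AKT activation by PI3K",
    "RAC1": "RAC1 GTPase: integrin-driven, restrained by CAV1 (up in knockout)",
    "Cdc42": "Cdc42 GTPase activation by Galpha12/13-coupled receptor ligands",
    "ARP2_3": "ARP2/3 actin nucleation downstream of RAC1/Cdc42",
    "F_actin": "filamentous-actin polymerization at the integrin contact",
    "Th1_Signal": "Th1-skewing cytokine input (IFN-gamma R, IL-12+IL-18, "
                  "IL-27, type-I IFN)",
    "GATA3": "GATA3 Th2 program: restrained by CAV1 and by Th1 cytokines",
    "Gamma_Chain": "common gamma-chain cytokine input (IL-2/4/9/15/21)",
    "STAT3_Signal": "STAT3-activating cytokine input (IL-6/10/21/22/23)",
    "Treg_Skew": "TGF-beta-driven regulatory skew in the absence of Th1 input",
    "cAMP_PKA": "GalphaS-coupled cAMP/PKA tone",
    "Survival": "cell-survival endpoint (AKT or cytokine-driven)",
    "Proliferation": "proliferation endpoint: ERK and NF-kB without "
                     "suppressive tone",
    "Cytoskeletal_Rearrangement": "cytoskeletal-rearrangement endpoint "
                                  "(immune-synapse actin remodeling)",
}

#: SHA-256 of the canonical rule text (format_rules of the built model)
REFERENCE_MODEL_SHA256 = (
    "96848e2e7db8ddac39f6a44469dccae0e81a8dc2c813278e5d9abd960e2054e4"
)


def reference_rules_text() -> str:
    return _RULES


def build_reference_model() -> LogicalNetwork:
    """The packaged, versioned reference model (deterministic)."""
    net = parse_rules_text(_RULES, name="cav1_cd4_tcell_reference", version="1.0")
    nodes = []
    for name in net.names:
        spec = net[name]
        note = ANNOTATIONS.get(name, "")
        nodes.append(NodeSpec(spec.name, spec.kind, spec.rule, annotation=note))
    return LogicalNetwork(nodes, name=net.name, version="1.0")


def reference_model_digest(network: LogicalNetwork = None) -> str:
    """SHA-256 digest of the canonical rule serialization."""
    if network is None:
        network = build_reference_model()
    return hashlib.sha256(format_rules(network).encode("utf-8")).hexdigest()


# ---------------------------------------------------------------------------
# Edge manifest
# ---------------------------------------------------------------------------

def _edge_signs(expr: Expr, negated: bool = False) -> List[Tuple[str, str]]:
    if isinstance(expr, Var):
        return [(expr.name, "inhibition" if negated else "activation")]
    if isinstance(expr, Not):
        return _edge_signs(expr.child, not negated)
    if isinstance(expr, (And, Or)):
        return _edge_signs(expr.left, negated) + _edge_signs(expr.right, negated)
    return []


def build_manifest(network: LogicalNetwork = None) -> List[Dict[str, str]]:
    """Edge list (source, target, sign, note) derived from the rules."""
    if network is None:
        network = build_reference_model()
    rows = []
    for name in network.internal_names:
        spec = network[name]
        seen = set()
        for source, sign in _edge_signs(spec.rule.expression):
            if (source, sign) in seen:
                continue
            seen.add((source, sign))
            rows.append({
                "source": source,
                "target": name,
                "sign": sign,
                "note": spec.annotation,
            })
    return rows


def manifest_tsv(network: LogicalNetwork = None) -> str:
    rows = build_manifest(network)
    lines = ["source\ttarget\tsign\tnote"]
    for r in rows:
        lines.append(f"{r['source']}\t{r['target']}\t{r['sign']}\t{r['note']}")
    return "\n".join(lines) + "\n"


def packaged_rules_path():
    return resources.files("cav1net").joinpath("data/reference_tcell.rules")


def packaged_sbml_path():
    return resources.files("cav1net").joinpath("data/reference_tcell.sbml")
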