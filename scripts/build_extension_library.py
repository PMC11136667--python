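"""Regenerate the shipped pathway-extension YAML library.

The YAML files under src/methyloflux/data/extensions are the shipped source
of record; this script rebuilds them from the definitions below and audits
elemental balance of the full extended model."""
from methyloflux.model import Metabolite, Reaction, PathwayExtension, load_model, extend_model, validate_mass_balance

from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "src" / "methyloflux" / "data" / "extensions"
B = 1000.0


def R(rid, name, stoich, lb, ub=B):
    return Reaction(id=rid, name=name, stoichiometry=stoich, lower_bound=lb, upper_bound=ub)


def M(mid, name, formula, charge, comp):
    return Metabolite(id=mid, name=name, compartment=comp, formula=formula, charge=charge)


rump_base = PathwayExtension(
    name="rump_base",
    new_metabolites=[
        M("meoh_c", "Methanol", "CH4O", 0, "c"),
        M("meoh_e", "Methanol", "CH4O", 0, "e"),
        M("fald_c", "Formaldehyde", "CH2O", 0, "c"),
        M("h6p_c", "D-arabino-3-hexulose 6-phosphate", "C6H11O9P", -2, "c"),
        M("s17bp_c", "Sedoheptulose 1,7-bisphosphate", "C7H12O13P2", -4, "c"),
        M("2ddg6p_c", "2-dehydro-3-deoxy-D-gluconate 6-phosphate", "C6H8O9P", -3, "c"),
    ],
    add=[
        R("MEDH", "methanol dehydrogenase (NAD)", {"meoh_c": -1, "nad_c": -1, "fald_c": 1, "nadh_c": 1, "h_c": 1}, 0),
        R("HPS", "3-hexulose-6-phosphate synthase", {"fald_c": -1, "ru5p__D_c": -1, "h6p_c": 1}, 0),
        R("PHI", "6-phospho-3-hexuloisomerase", {"h6p_c": -1, "f6p_c": 1}, 0),
        R("FALDDH", "formaldehyde dehydrogenase (lumped, glutathione-independent)",
          {"fald_c": -1, "nad_c": -1, "h2o_c": -1, "for_c": 1, "nadh_c": 1, "h_c": 2}, 0),
        R("FDH", "formate dehydrogenase (NAD)", {"for_c": -1, "nad_c": -1, "co2_c": 1, "nadh_c": 1}, 0),
        R("MEOHt", "methanol diffusion", {"meoh_e": -1, "meoh_c": 1}, -B),
        R("EX_meoh_e", "methanol exchange", {"meoh_e": -1}, -60.0),
        R("FBA3", "sedoheptulose-1,7-bisphosphate aldolase", {"dhap_c": -1, "e4p_c": -1, "s17bp_c": 1}, -B),
        R("SBP17BPase", "sedoheptulose-1,7-bisphosphatase", {"s17bp_c": -1, "h2o_c": -1, "s7p_c": 1, "pi_c": 1}, 0),
        R("EDD", "6-phosphogluconate dehydratase", {"6pgc_c": -1, "2ddg6p_c": 1, "h2o_c": 1}, 0),
        R("EDA", "2-dehydro-3-deoxy-phosphogluconate aldolase", {"2ddg6p_c": -1, "g3p_c": 1, "pyr_c": 1}, 0),
    ],
    remove=["ME1", "ME2"],
    bound_changes={"EX_glc__D_e": (0.0, B)},
)

ed_ta = PathwayExtension(name="ed_ta", remove=["TPI"])
fba_ta = PathwayExtension(name="fba_ta", remove=["EDD", "EDA"])
c1_salvage = PathwayExtension(
    name="c1_salvage",
    bound_changes={"FALDDH": (-B, B), "FDH": (-B, B)},
)

product_lactate = PathwayExtension(
    name="product_lactate",
    new_metabolites=[
        M("lac__L_c", "L-lactate", "C3H5O3", -1, "c"),
        M("lac__L_e", "L-lactate", "C3H5O3", -1, "e"),
    ],
    add=[
        R("LDH_L", "L-lactate dehydrogenase", {"pyr_c": -1, "nadh_c": -1, "h_c": -1, "lac__L_c": 1, "nad_c": 1}, 0),
        R("L_LACt2r", "L-lactate proton symport", {"lac__L_e": -1, "h_e": -1, "lac__L_c": 1, "h_c": 1}, -B),
        R("EX_lac__L_e", "L-lactate exchange", {"lac__L_e": -1}, 0),
    ],
)

product_phb = PathwayExtension(
    name="product_phb",
    new_metabolites=[M("phb_c", "PHB monomer (3-hydroxybutanoate unit)", "C4H6O2", 0, "c")],
    add=[
        R("PHB_SYN", "PHB monomer synthesis (phaCAB lump)",
          {"accoa_c": -2, "nadph_c": -1, "h_c": -1, "phb_c": 1, "coa_c": 2, "nadp_c": 1}, 0),
        R("DM_phb_c", "PHB monomer demand", {"phb_c": -1}, 0),
    ],
)

product_itaconate = PathwayExtension(
    name="product_itaconate",
    new_metabolites=[
        M("itacon_c", "Itaconate", "C5H4O4", -2, "c"),
        M("itacon_e", "Itaconate", "C5H4O4", -2, "e"),
    ],
    add=[
        R("CADA", "cis-aconitate decarboxylase", {"acon_C_c": -1, "h_c": -1, "itacon_c": 1, "co2_c": 1}, 0),
        R("ITACONt", "itaconate export", {"itacon_c": -1, "itacon_e": 1}, 0),
        R("EX_itacon_e", "itaconate exchange", {"itacon_e": -1}, 0),
    ],
)

_PABA_METS = [
    M("4abz_c", "4-aminobenzoate", "C7H6NO2", -1, "c"),
    M("4abz_e", "4-aminobenzoate", "C7H6NO2", -1, "e"),
]

product_paba = PathwayExtension(
    name="product_paba",
    new_metabolites=list(_PABA_METS),
    add=[
        R("PABS", "4-aminobenzoate synthesis (chorismate pathway lump, glutamine amide donor)",
          {"e4p_c": -1, "pep_c": -2, "atp_c": -1, "nadph_c": -1, "gln__L_c": -1,
           "4abz_c": 1, "pyr_c": 1, "glu__L_c": 1, "adp_c": 1, "nadp_c": 1, "pi_c": 4, "h_c": 1}, 0),
        R("PABAt", "4-aminobenzoate export", {"4abz_c": -1, "4abz_e": 1}, 0),
        R("EX_4abz_e", "4-aminobenzoate exchange", {"4abz_e": -1}, 0),
    ],
)

# alternative amide-nitrogen accounting: ammonium donor, glutamine-recharge
# ATP not charged to the product pathway
product_paba_nh4 = PathwayExtension(
    name="product_paba_nh4",
    new_metabolites=list(_PABA_METS),
    add=[
        R("PABS", "4-aminobenzoate synthesis (chorismate pathway lump, ammonium donor)",
          {"e4p_c": -1, "pep_c": -2, "atp_c": -1, "nadph_c": -1, "nh4_c": -1,
           "4abz_c": 1, "pyr_c": 1, "adp_c": 1, "nadp_c": 1, "pi_c": 4, "h2o_c": 1, "h_c": 1}, 0),
        R("PABAt", "4-aminobenzoate export", {"4abz_c": -1, "4abz_e": 1}, 0),
        R("EX_4abz_e", "4-aminobenzoate exchange", {"4abz_e": -1}, 0),
    ],
)

exts = [rump_base, ed_ta, fba_ta, c1_salvage, product_lactate, product_phb,
        product_itaconate, product_paba, product_paba_nh4]
for ext in exts:
    ext.to_yaml(OUT / f"{ext.name}.yaml")
    print("wrote", ext.name)

# sanity: build and audit elemental balance of everything we shipped
core = load_model(ROOT / "src" / "methyloflux" / "data" / "e_coli_core.json")
m = extend_model(core, rump_base)
m = extend_model(m, ed_ta)
for p in [product_lactate, product_phb, product_itaconate, product_paba]:
    m = extend_model(m, p)
report = validate_mass_balance(m)
bad = {k: v for k, v in report.items() if v != "unknown"}
print("imbalances:", bad)
print("unknown-formula reactions:", [k for k, v in report.items() if v == "unknown"])
assert not bad, bad
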