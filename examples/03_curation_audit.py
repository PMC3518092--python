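"""Model quality control: dead-ends, unbalanced reactions, redundancy.

A network with planted flaws is audited: dead-end metabolites (only
produced or only consumed — pathway gaps), duplicate reactions and
isolated fragments.  The balance audit is shown on the classic database
error of a dropped proton in hexokinase.
"""

from fluxkit import MetabolicModel, Metabolite, Reaction, check_balance
from fluxkit.curation import find_deadends, find_redundant
from fluxkit.model import parse_formula
from fluxkit.synth import SyntheticSpec, make_random_network

model, ledger = make_random_network(
    SyntheticSpec(seed=7, planted_deadends=3, planted_duplicates=2,
                  planted_isolated=1)
)

dd = find_deadends(model)
print(f"dead-end metabolites found: {dd.deadends}")
print(f"  (generator planted:       {ledger['deadends']})")
red = find_redundant(model)
print(f"duplicate reaction groups: {red.duplicate_groups}")
print(f"isolated reactions:        {red.isolated}")

# balance audit: glc + ATP -> g6p + ADP, written WITHOUT the product H+
m = MetabolicModel(
    metabolites=[
        Metabolite("glc[c]", compartment="c", formula=parse_formula("C6H12O6"), charge=0),
        Metabolite("atp[c]", compartment="c", formula=parse_formula("C10H12N5O13P3"), charge=-4),
        Metabolite("g6p[c]", compartment="c", formula=parse_formula("C6H11O9P"), charge=-2),
        Metabolite("adp[c]", compartment="c", formula=parse_formula("C10H12N5O10P2"), charge=-3),
    ],
    reactions=[Reaction("HEX1", {"glc[c]": -1, "atp[c]": -1, "g6p[c]": 1, "adp[c]": 1})],
)
entry = check_balance(m.reactions[0], m)
print(f"\nhexokinase without product proton: {entry.status}")
print(f"  element deficit {entry.element_deficit}, charge deficit "
      f"{entry.charge_deficit:g}")
print(f"  suggested fix: {entry.suggested_fix}")
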