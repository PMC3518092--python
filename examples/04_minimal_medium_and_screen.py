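"""Minimal-medium prediction and carbon-substrate screening.

Greedy elimination opens every candidate exchange and closes them one at
a time, keeping a closure only if growth survives; the result is locally
minimal (closing any retained nutrient abolishes growth).  Substrate
screening then swaps the carbon source and asks which substrates support
growth, scored against observed assimilation calls with GN/NG bookkeeping
(GN: grows in vivo but not in silico; NG: the reverse).
"""

from fluxkit import compare_predictions, determine_minimal_media, screen_substrates
from fluxkit.synth import SyntheticSpec, make_core_network

model = make_core_network(SyntheticSpec()).model

medium = determine_minimal_media(model, "EX_glc", ["EX_glc", "EX_co2"],
                                 carbon_lb=-10.0)
print("minimal medium (exchange id -> bounds, negative lb = uptake):")
for rid, bounds in medium.items():
    print(f"  {rid}: {bounds}")

base = {"EX_co2": (-1000.0, 1000.0)}  # carbon-free base medium
observed = {"glc[e]": True, "co2[e]": False, "unknown_sugar[e]": True}
screen = screen_substrates(model, base, list(observed), observed=observed)
print("\nsubstrate screen (sole carbon source, uptake bound 20):")
for call in screen.calls:
    print(f"  {call.substrate:18s} predicted {'+' if call.predicted else '-'} "
          f"observed {'+' if call.observed else '-'}  growth {call.growth:.3f} "
          f"{call.reason}")
cmp_ = compare_predictions(screen)
print(f"accuracy {cmp_.n_agree}/{cmp_.n_total} = {cmp_.accuracy:.0%}; "
      f"GN {cmp_.gn}, NG {cmp_.ng}")
print("the GN substrate marks a capability the model is missing — a "
      "curation target.")
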