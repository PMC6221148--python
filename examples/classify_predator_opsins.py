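"""Classify the packaged avian predator SWS1 opsin windows as UVS or VS.

Each bird's short-wavelength opsin fragment is reduced to the 11-residue
spectral-tuning window (sites 84-94); cysteine at site 90 or
phenylalanine at site 86 marks an ultraviolet-shifted (UVS) pigment.
"""

import mimicvis as mv

calls = mv.classify_fasta(mv.packaged_fixture_path())
for call in calls:
    sites = call.window.key_sites
    print(f"{call.species:28s} 86={sites[86]} 90={sites[90]} "
          f"93={sites[93]}  ->  {call.type:3s} ({call.rule_fired})")

from mimicvis.opsin import summarize_calls  # noqa: E402
print("\nSummary:", summarize_calls(calls))
print("A UVS predator sees further into the ultraviolet than a VS one, "
      "changing which wing-color differences it can resolve.")
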