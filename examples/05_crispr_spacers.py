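"""CRISPR spacer matching and host assignment.

Spacers are planted in a phage genome with controlled edits; matching seeds
on exact 10-mers, extends semi-globally, and enforces the gap caps (<=20% of
the spacer, <=5 bp per event, gaps count as mismatches).  Assignment keeps
only hits with at most 1 effective mismatch.
"""

import phagetax as pt
from phagetax.spacers import Spacer, find_spacer_hits

phage = pt.generate_ancestor(10_000, 0.38, 4)
phage.id = "phage1"
truth = pt.plant_spacers(phage, 6, edits=[(0, ()), (1, ()), (2, ())], seed=1)

spacers = []
for st in truth.spacers:
    host = f"host_{st.n_substitutions}mm"
    spacers.append(Spacer(f"{host}|{st.spacer_id}", host, st.sequence))
    hits = find_spacer_hits(spacers[-1], phage)
    best = hits[0].effective_mismatches if hits else "none"
    print(f"{st.spacer_id}: planted {st.n_substitutions} substitutions "
          f"-> best hit {best} effective mismatches")

table = pt.assign_phage_to_host(spacers, [phage], max_mismatch=1)
print("\nhost-phage assignments (<=1 effective mismatch):")
print(table.to_string(index=False))
print("\nhosts whose spacers carry 2 mismatches are correctly not assigned")
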