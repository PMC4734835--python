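"""Find unproducible compounds and propose reactions that fix them.

The blocked fixture contains an orphan conversion C -> D where neither
C nor D is connected to the rest of the network.  gapfind reports both
as blocked (C as a root gap: nothing can produce it at all); gapfill,
given a database that also contains an exchange for D, proposes the
single cheapest addition.
"""

from gemkit import (
    Compound, ReactionEntry, apply_proposal, gapfill, gapfind,
    make_fixture, parse_equation)

model = make_fixture("blocked")
report = gapfind(model)
print("Blocked compounds:", ", ".join(
    str(c) for c in sorted(report.blocked_compounds, key=str)))
print("Root gaps:", ", ".join(
    str(c) for c in sorted(report.root_gaps, key=str)))

database = model.copy()
database.model_subset = set(model.reactions)
database.add_reaction(ReactionEntry("EX_D", parse_equation("D[c] <=>")))

proposal = gapfill(
    model, database, targets={Compound("D", "c")}, allow_reversals=False)
print("\nProposal for D:", proposal.added_reactions,
      f"(penalty {proposal.penalty:g})")

filled = apply_proposal(model, database, proposal)
print("Blocked after applying the proposal:",
      sorted(map(str, gapfind(filled).blocked_compounds)))
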