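"""Localize a stoichiometric inconsistency with the mass checks.

Builds a two-reaction model of glucose-phosphate isomerization in which
one copy of the reaction carries two stray protons.  The compound-based
check names the compound that cannot carry mass; the reaction-based
check, after marking the balanced copy as checked, pins the residual on
the broken equation.
"""

from gemkit import make_fixture, masscheck_compounds, masscheck_reactions

model = make_fixture("glucose_pair")
for rid, entry in model.reactions.items():
    print(f"{rid}: {entry.equation.render()}")

compound_result = masscheck_compounds(model, exclude=set())
print("\nCompounds unable to attain positive mass:",
      ", ".join(str(c) for c in compound_result.flagged))

reaction_result = masscheck_reactions(
    model, exclude=set(), checked={"RR08939"})
for rid, r in reaction_result.flagged:
    print(f"Unbalanced reaction {rid}: "
          f"left-minus-right residual {-r:+g} H")

# The +2 residual says the left side of RR00610 carries two hydrogen
# atoms too many -- exactly the two stray protons.
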