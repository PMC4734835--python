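"""SBML import (strict and repairing) and export round trips.

The export path is additionally validated against independent parsers:
libsbml checks specification compliance and cobrapy re-optimizes an
exported model, cross-checking our own FBA result.
"""

import warnings

import pytest

from gemkit import (
    Compound, Direction, fba, import_sbml, export_sbml, make_fixture,
    matrix_view)
from gemkit.io import SbmlError
from gemkit.io.sbml import detect_biomass
from tests.conftest import random_models

L2_HEAD = ('<?xml version="1.0" encoding="UTF-8"?>\n'
           '<sbml xmlns="http://www.sbml.org/sbml/level2" '
           'level="2" version="1">\n')


def _write(tmp_path, body, head=L2_HEAD):
    path = tmp_path / "model.xml"
    path.write_text(head + body + "</sbml>\n")
    return path


MINIMAL = """
<model id="mini" name="mini">
 <listOfCompartments><compartment id="c"/></listOfCompartments>
 <listOfSpecies>
  <species id="M_a_c" name="a" compartment="c"/>
  <species id="M_b_c" name="b" compartment="c"/>
 </listOfSpecies>
 <listOfReactions>
  <reaction id="R_r1" reversible="false">
   <listOfReactants>
    <speciesReference species="M_a_c" stoichiometry="1"/>
   </listOfReactants>
   <listOfProducts>
    <speciesReference species="M_b_c" stoichiometry="2"/>
   </listOfProducts>
  </reaction>
 </listOfReactions>
</model>
"""


def test_minimal_level2_strict(tmp_path):
    model, report = import_sbml(_write(tmp_path, MINIMAL), strict=True)
    assert list(model.reactions) == ["r1"]
    assert not report.warnings and not report.repairs
    eq = model.reactions["r1"].equation
    assert eq.direction is Direction.FORWARD
    assert eq.right[0][1] == 2


def test_lax_mode_fires_no_repairs_on_valid_file(tmp_path):
    _, report = import_sbml(_write(tmp_path, MINIMAL), strict=False)
    assert not report.repairs


L1_DECIMAL = """
<model name="old">
 <listOfCompartments><compartment name="c"/></listOfCompartments>
 <listOfSpecies>
  <specie name="A" compartment="c"/>
  <specie name="B" compartment="c"/>
 </listOfSpecies>
 <listOfReactions>
  <reaction name="r1" reversible="true">
   <listOfReactants>
    <speciesReference species="A" stoichiometry="0.5"/>
   </listOfReactants>
   <listOfProducts>
    <speciesReference species="B" stoichiometry="1"/>
   </listOfProducts>
  </reaction>
 </listOfReactions>
</model>
"""

L1_HEAD = ('<?xml version="1.0" encoding="UTF-8"?>\n'
           '<sbml xmlns="http://www.sbml.org/sbml/level1" '
           'level="1" version="2">\n')


def test_level1_decimal_stoichiometry(tmp_path):
    path = _write(tmp_path, L1_DECIMAL, L1_HEAD)
    with pytest.raises(SbmlError, match="decimal"):
        import_sbml(path, strict=True)
    model, report = import_sbml(path, strict=False)
    assert ("decimal_stoichiometry", "r1") in report.repairs
    assert float(model.reactions["r1"].equation.left[0][1]) == 0.5


BOUNDARY_SUFFIX = """
<model id="bsuf">
 <listOfCompartments><compartment id="c"/></listOfCompartments>
 <listOfSpecies>
  <species id="M_a_c" compartment="c"/>
  <species id="M_a_b" compartment="c"/>
 </listOfSpecies>
 <listOfReactions>
  <reaction id="R_ex" reversible="true">
   <listOfReactants>
    <speciesReference species="M_a_c"/>
   </listOfReactants>
   <listOfProducts>
    <speciesReference species="M_a_b"/>
   </listOfProducts>
  </reaction>
 </listOfReactions>
</model>
"""


def test_boundary_suffix_species_creates_exchange(tmp_path):
    path = _write(tmp_path, BOUNDARY_SUFFIX)
    with pytest.raises(SbmlError, match="_b"):
        import_sbml(path, strict=True)
    model, report = import_sbml(path, strict=False)
    assert ("boundary_suffix", "M_a_b") in report.repairs
    eq = model.reactions["ex"].equation
    assert len(eq.left) == 1 and len(eq.right) == 0  # became an exchange
    assert model.is_exchange("ex")


UNDEFINED = """
<model id="ghost">
 <listOfCompartments><compartment id="c"/></listOfCompartments>
 <listOfSpecies>
  <species id="M_a_c" compartment="c"/>
 </listOfSpecies>
 <listOfReactions>
  <reaction id="R_r" reversible="false">
   <listOfReactants>
    <speciesReference species="M_a_c"/>
    <speciesReference species="M_ghost_c"/>
   </listOfReactants>
  </reaction>
 </listOfReactions>
</model>
"""


def test_undefined_species_dropped_in_lax_mode(tmp_path):
    path = _write(tmp_path, UNDEFINED)
    with pytest.raises(SbmlError, match="undefined"):
        import_sbml(path, strict=True)
    model, report = import_sbml(path, strict=False)
    assert ("undefined_species", "R_r") in report.repairs
    assert len(model.reactions["r"].equation.left) == 1


CONFLICT = """
<model id="conflict">
 <listOfCompartments><compartment id="c"/></listOfCompartments>
 <listOfSpecies>
  <species id="M_a_c" compartment="c"/>
  <species id="M_b_c" compartment="c"/>
 </listOfSpecies>
 <listOfReactions>
  <reaction id="R_r" reversible="false">
   <listOfReactants><speciesReference species="M_a_c"/></listOfReactants>
   <listOfProducts><speciesReference species="M_b_c"/></listOfProducts>
   <kineticLaw>
    <listOfParameters>
     <parameter id="LOWER_BOUND" value="-1000"/>
     <parameter id="UPPER_BOUND" value="1000"/>
    </listOfParameters>
   </kineticLaw>
  </reaction>
 </listOfReactions>
</model>
"""


def test_reversibility_conflict_keeps_cobra_bounds(tmp_path):
    path = _write(tmp_path, CONFLICT)
    with pytest.raises(SbmlError, match="irreversible"):
        import_sbml(path, strict=True)
    model, report = import_sbml(path, strict=False)
    assert ("reversibility_conflict", "R_r") in report.repairs
    assert matrix_view(model).bounds["r"] == (-1000.0, 1000.0)
    # Conflict recorded again when bounds are resolved.
    assert any("irreversible" in w for w in matrix_view(model).warnings)


OBJECTIVE = """
<model id="obj">
 <listOfCompartments><compartment id="c"/></listOfCompartments>
 <listOfSpecies>
  <species id="M_a_c" compartment="c"/>
 </listOfSpecies>
 <listOfReactions>
  <reaction id="R_BIO" reversible="false">
   <listOfReactants><speciesReference species="M_a_c"/></listOfReactants>
   <kineticLaw>
    <listOfParameters>
     <parameter id="OBJECTIVE_COEFFICIENT" value="1"/>
    </listOfParameters>
   </kineticLaw>
  </reaction>
 </listOfReactions>
</model>
"""


def test_biomass_from_objective_coefficient(tmp_path):
    model, report = import_sbml(_write(tmp_path, OBJECTIVE))
    assert model.biomass == "BIO"


def test_biomass_fallback_to_id_search():
    from gemkit import Model, ReactionEntry, parse_equation

    model = Model()
    model.add_reaction(ReactionEntry("r1", parse_equation("A[c] => B[c]")))
    model.add_reaction(
        ReactionEntry("R_biomass_core", parse_equation("B[c] =>")))
    assert detect_biomass(model, {}) == "R_biomass_core"
    assert detect_biomass(Model(), {}) is None


@pytest.mark.parametrize("kind", ["chain", "blocked", "loop", "branched"])
def test_export_import_round_trip_fixture(tmp_path, kind):
    model = make_fixture(kind)
    path = tmp_path / "out.xml"
    export_sbml(model, path)
    back, report = import_sbml(path, strict=True)
    assert not report.repairs
    _assert_equivalent(model, back)


def test_export_import_round_trip_random(tmp_path):
    for i, model in enumerate(random_models(5)):
        path = tmp_path / f"{i}.xml"
        export_sbml(model, path)
        back, _ = import_sbml(path, strict=True)
        _assert_equivalent(model, back)


def _assert_equivalent(model, back):
    matrix, matrix_back = matrix_view(model), matrix_view(back)
    assert set(matrix_back.reactions) == set(matrix.reactions)
    assert set(matrix_back.compounds) == set(matrix.compounds)
    for (compound, rid), value in matrix.entries.items():
        assert matrix_back.value(compound, rid) == value
    for rid in matrix.reactions:
        assert matrix_back.bounds[rid] == matrix.bounds[rid]
    assert back.biomass == model.biomass


def test_exported_file_passes_independent_validation(tmp_path, chain):
    libsbml = pytest.importorskip("libsbml")
    path = tmp_path / "chain.xml"
    export_sbml(chain, path)
    document = libsbml.readSBMLFromFile(str(path))
    assert document.getNumErrors(libsbml.LIBSBML_SEV_ERROR) == 0


def test_cobra_reproduces_fba_on_export(tmp_path, chain):
    cobra = pytest.importorskip("cobra")
    path = tmp_path / "chain.xml"
    export_sbml(chain, path)
    ours = fba(chain).objective_value
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cobra_model = cobra.io.read_sbml_model(str(path))
        cobra_model.objective = "BIO"
        theirs = cobra_model.optimize().objective_value
    assert theirs == pytest.approx(ours, abs=1e-6)
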