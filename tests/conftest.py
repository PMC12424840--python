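import pytest

from pipermine.dictionary import compile_dictionary
from pipermine.ingest import CompoundRecord, Dataset, FormulaRecord


@pytest.fixture(scope="session")
def default_dictionary():
    return compile_dictionary()


def make_dataset(formula_defs, species_compounds):
    """Hand-build a dataset.

    ``formula_defs``: {formula_id: (species set, indications list)};
    ``species_compounds``: {species: compound key set}.
    """
    ds = Dataset()
    keys = sorted({ck for cks in species_compounds.values() for ck in cks})
    for ck in keys:
        ds.compounds[ck] = CompoundRecord(compound_key=ck, name=ck)
    for sp, cks in species_compounds.items():
        ds.add_species(sp)
        for ck in cks:
            ds.link(sp, ck)
    for fid, (species, indications) in formula_defs.items():
        ds.formulas[fid] = FormulaRecord(
            formula_id=fid, species=set(species),
            indications=list(indications),
        )
        for sp in species:
            ds.add_species(sp)
    return ds


@pytest.fixture
def hand_dataset():
    """Four formulas all containing compound c1; category pattern
    {Pain}, {Pain}, {Pain, Sleep}, {} — the worked association example."""
    return make_dataset(
        {
            "f1": ({"Piper nigrum"}, ["joint pain"]),
            "f2": ({"Piper nigrum"}, ["chronic headache"]),
            "f3": ({"Piper longum"}, ["aching joints", "insomnia"]),
            "f4": ({"Piper longum"}, ["cough"]),
        },
        {"Piper nigrum": {"c1"}, "Piper longum": {"c1", "c2"}},
    )
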