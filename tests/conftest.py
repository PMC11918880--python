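import pytest

from sasscore import (
    MolecularFinding,
    PhenotypeRecord,
    StructuralVariant,
    default_rubric_path,
    load_domains,
    load_rubric,
)


@pytest.fixture(scope="session")
def schema():
    return load_rubric(default_rubric_path())


@pytest.fixture(scope="session")
def domains():
    return load_domains()


def make_record(iid="P1", sex="female", age=10.0, **levels):
    return PhenotypeRecord(individual_id=iid, sex=sex, age_years=age, levels=levels)


@pytest.fixture()
def full_record(schema):
    """A record with every category observed at a mid-range level."""
    levels = {c.name: min(1, c.max_points) for c in schema.categories}
    return make_record(**levels)


def subcategory_panel():
    """One hand-built finding per molecular subcategory rule branch.

    Expected labels written down independently from the classification
    rules (recurrent CUT1 missense; missense by domain; truncating split
    at codon 350; deletion split at 6 Mb; intragenic deletion; canonical
    splice).
    """
    return [
        (MolecularFinding(individual_id="a", hgvs_p="p.Arg389Cys"), "missense", "arg389cys"),
        (MolecularFinding(individual_id="b", hgvs_p="p.Arg429Gln"), "missense", "missense_cut1"),
        (MolecularFinding(individual_id="c", hgvs_p="p.Gly515Asp"), "missense", "missense_cut2"),
        (MolecularFinding(individual_id="d", hgvs_p="p.Ser649Leu"), "missense", "missense_hox"),
        (MolecularFinding(individual_id="e", hgvs_p="p.Ala300Val"), "missense", "missense_other"),
        (MolecularFinding(individual_id="f", hgvs_p="p.Gln100Ter"), "null", "null_before_350"),
        (MolecularFinding(individual_id="g", hgvs_p="p.Glu417Glyfs*13"), "null", "null_at_after_350"),
        (
            MolecularFinding(
                individual_id="h",
                structural=StructuralVariant(kind="deletion", size_mb=2.5, intragenic=False),
            ),
            "chromosomal",
            "chrom_del_lt6mb",
        ),
        (
            MolecularFinding(
                individual_id="i",
                structural=StructuralVariant(kind="deletion", size_mb=8.2, intragenic=False),
            ),
            "chromosomal",
            "chrom_del_ge6mb",
        ),
        (
            MolecularFinding(
                individual_id="j",
                structural=StructuralVariant(kind="deletion", intragenic=True),
            ),
            "null",
            "intragenic_del",
        ),
        (MolecularFinding(individual_id="k", hgvs_c="c.1741-2A>G"), "null", "splice"),
    ]


@pytest.fixture(scope="session")
def panel():
    return subcategory_panel()
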