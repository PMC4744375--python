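import textwrap

import pytest

from oncoprofiler import formats, mutation, simulate


TOY_BARCODES = [
    "TCGA-A1-0001-01A-11D-A001-01",
    "TCGA-A1-0002-01A-11D-A001-01",
    "TCGA-A1-0003-01A-11D-A001-01",
    "TCGA-A1-0004-01A-11D-A001-01",
]


@pytest.fixture
def toy_maf(tmp_path):
    """The 4-sample toy cohort: S1 has two missense records for G,
    S2 one nonsense record; S3 and S4 are assayed but unmutated."""
    path = tmp_path / "toy.maf.txt"
    path.write_text(
        textwrap.dedent(
            f"""\
            #version 2.4
            Hugo_Symbol\tVariant_Classification\tTumor_Sample_Barcode
            G\tMissense_Mutation\t{TOY_BARCODES[0]}
            G\tMissense_Mutation\t{TOY_BARCODES[0]}
            G\tNonsense_Mutation\t{TOY_BARCODES[1]}
            """
        )
    )
    return path


@pytest.fixture
def toy_cohort():
    barcodes = [formats.parse_barcode(b) for b in TOY_BARCODES]
    return mutation.CohortIndex.from_roster("TOY", barcodes)


@pytest.fixture(scope="session")
def small_cohort():
    """One in-memory synthetic entity shared by read-only tests."""
    spec = simulate.CohortSpec(
        entity="BRCA",
        n_participants=30,
        normal_fraction=0.5,
        seed=11,
        genes=[
            simulate.GeneSpec(
                "TP53", 7157, mutation_rate=0.4, meth_delta={"Body": 0.3},
                expr_outliers=((2, 4.0),),
                cnv_category_probs=(0.05, 0.10, 0.60, 0.15, 0.10),
            ),
            simulate.GeneSpec("VHL", 7428, mutation_rate=0.05),
            simulate.GeneSpec("TSHZ3", 57616, mutation_rate=0.0),
        ],
    )
    return simulate.simulate_cohort(spec)


@pytest.fixture(scope="session")
def small_cohort_dir(tmp_path_factory):
    """The same entity written to disk in the four pinned dialects."""
    spec = simulate.CohortSpec(
        entity="BRCA",
        n_participants=30,
        normal_fraction=0.5,
        seed=11,
        genes=[
            simulate.GeneSpec(
                "TP53", 7157, mutation_rate=0.4, meth_delta={"Body": 0.3},
                expr_outliers=((2, 4.0),),
                cnv_category_probs=(0.05, 0.10, 0.60, 0.15, 0.10),
            ),
            simulate.GeneSpec("VHL", 7428, mutation_rate=0.05),
            simulate.GeneSpec("TSHZ3", 57616, mutation_rate=0.0),
        ],
    )
    outdir = tmp_path_factory.mktemp("cohort")
    simulate.generate(spec, outdir)
    return outdir
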