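import textwrap

import pytest

from genomering import seqio, synthetic


@pytest.fixture
def small_genome():
    return synthetic.synth_genome(5_000, 0.5, seed=11, id="ref")


@pytest.fixture
def refmap(small_genome):
    return seqio.build_reference_map([small_genome])


@pytest.fixture
def mini_ace(tmp_path):
    """One 20-base contig, two 12-base reads at padded offsets 1 and 9:
    pileup is 1 on [0,8), 2 on [8,12), 1 on [12,20)."""
    contig = "ACGTACGTACGTACGTACGT"
    text = textwrap.dedent(f"""\
        AS 1 2

        CO contig1 20 2 1 U
        {contig}

        BQ

        AF read1 U 1
        AF read2 U 9

        RD read1 12 0 0
        {contig[0:12]}

        QA 1 12 1 12

        RD read2 12 0 0
        {contig[8:20]}

        QA 1 12 1 12
        """)
    path = tmp_path / "mini.ace"
    path.write_text(text)
    return path


@pytest.fixture
def mini_genbank(tmp_path):
    """Hand-written minimal GenBank: 8 bp ORIGIN, three misc_features whose
    /note values are 'Sp 1', 'SpLE 4' and 'other'."""
    text = textwrap.dedent("""\
        LOCUS       MINI                       8 bp    DNA     linear   BCT 01-JAN-2000
        DEFINITION  minimal fixture.
        ACCESSION   MINI
        FEATURES             Location/Qualifiers
             source          1..8
                             /organism="synthetic"
             misc_feature    1..3
                             /note="Sp 1"
             misc_feature    4..6
                             /note="SpLE 4"
             misc_feature    7..8
                             /note="other"
        ORIGIN
                1 acgtacgt
        //
        """)
    path = tmp_path / "mini.gb"
    path.write_text(text)
    return path
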