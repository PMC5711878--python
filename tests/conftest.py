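import pytest

from lwiscape import read_topology

# Rat TRPV1 TM topology (1-based inclusive) with loop/pore/motif annotations;
# N-terminus cytoplasmic.  Full-length rTRPV1 is 838 residues.
RAT_TOPOLOGY_TSV = "\n".join(
    [
        "#protein_id=rTRPV1\tn_term_side=cytoplasmic",
        "Transmembrane1\t429\t454",
        "Loop1\t455\t468",
        "Transmembrane2\t469\t497",
        "Loop2\t498\t510",
        "Transmembrane3\t511\t532",
        "Loop3\t533\t534",
        "Transmembrane4\t535\t556",
        "Loop4\t557\t569",
        "Transmembrane5\t570\t598",
        "Loop5\t599\t629",
        "Pore loop\t630\t642",
        "Loop6\t643\t655",
        "Transmembrane6\t656\t686",
        "N Terminal\t1\t428",
        "C Terminal\t687\t838",
        "CCM\t433\t447",
    ]
)

RAT_SEQ_LEN = 838


@pytest.fixture(scope="session")
def rat_topology():
    return read_topology(RAT_TOPOLOGY_TSV)
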