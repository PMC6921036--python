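import pytest

from cppqsar import Peptide, load_published_scale

#: The four reference CPPs with their published counts:
#: (id, sequence, length, n_arg, n_lys, n_his, hydrophilic ratio %)
REFERENCE_CPPS = [
    ("Pen", "RQIKIWFQNRRMKWKK", 16, 3, 4, 0, 63),
    ("Cys-Pen", "CRQIKIWFQNRRMKWKK", 17, 3, 4, 0, 59),
    ("pVEC", "LLIILRRRIRKQAHAHSK", 18, 4, 2, 2, 44),
    ("Cys-pVEC", "CLLIILRRRIRKQAHAHSK", 19, 4, 2, 2, 42),
]


@pytest.fixture(scope="session")
def scale():
    return load_published_scale()


@pytest.fixture(scope="session")
def pen():
    return Peptide("Pen", "RQIKIWFQNRRMKWKK")


@pytest.fixture(scope="session")
def reference_peptides():
    return [Peptide(name, seq) for name, seq, *_ in REFERENCE_CPPS]
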