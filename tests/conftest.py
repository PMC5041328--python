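import string

import pytest
from hypothesis import HealthCheck, settings, strategies as st

from samsa.annotation_io import AnnotationRecord, SourceDB
from samsa.aggregation import AbundanceTable
from samsa.synthetic_data import sim_community

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

# Text safe for the tab-delimited format: no tabs/newlines, no multi-annotation
# delimiter, no leading comment prefix, non-empty after stripping.
safe_text = st.text(
    alphabet=string.ascii_letters + string.digits + " _-.",
    min_size=1,
    max_size=25,
).filter(lambda s: s.strip() == s and s and not s.startswith("#"))


@st.composite
def annotation_records(draw, source_db=None):
    db = source_db or draw(st.sampled_from(list(SourceDB)))
    return AnnotationRecord(
        read_id=draw(safe_text),
        match_id=draw(safe_text),
        annotation_text=draw(safe_text),
        source_db=db,
        percent_identity=draw(
            st.one_of(st.none(), st.floats(0, 100, allow_nan=False))
        ),
        alignment_length=draw(st.one_of(st.none(), st.integers(1, 500))),
        evalue=draw(st.one_of(st.none(), st.floats(0, 1, allow_nan=False))),
    )


@st.composite
def abundance_tables(draw, min_features=1, max_features=40, integer=True):
    n = draw(st.integers(min_features, max_features))
    keys = draw(
        st.lists(safe_text, min_size=n, max_size=n, unique=True)
    )
    if integer:
        vals = draw(st.lists(st.integers(0, 10_000), min_size=n, max_size=n))
    else:
        vals = draw(
            st.lists(st.floats(0, 1e4, allow_nan=False), min_size=n, max_size=n)
        )
    return AbundanceTable(
        sample_id="hyp",
        source_db=SourceDB.REFSEQ_ORG,
        counts=dict(zip(keys, map(float, vals))),
    )


@pytest.fixture(scope="session")
def community():
    """A 30-taxon lognormal community with lineages, used across modules."""
    return sim_community(30, seed=101)


@pytest.fixture(scope="session")
def rrna_community():
    """Community with dominant rRNA and uneven per-phylum depletion."""
    return sim_community(
        30,
        seed=202,
        rrna_fraction=0.8,
        retention={
            "Firmicutes": 0.3,
            "Bacteroidetes": 0.05,
            "Proteobacteria": 0.7,
            "Actinobacteria": 1.0,
            "Verrucomicrobia": 0.5,
            "Euryarchaeota": 0.9,
        },
    )
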