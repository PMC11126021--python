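"""Hypothesis strategies shared across the suite."""

from hypothesis import strategies as st

from qsrare import make_table


@st.composite
def haplotype_tables(draw, max_h: int = 10, max_count: int = 30):
    """A small random valid haplotype table."""
    h = draw(st.integers(min_value=1, max_value=max_h))
    counts = draw(
        st.lists(st.integers(min_value=1, max_value=max_count), min_size=h, max_size=h)
    )
    return make_table([f"h{i:03d}" for i in range(h)], counts)
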