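import pytest

from glyloop import GeneratorParams, IndexStyle, generate_loricrin_protein

# loop-alphabet weights used for the two composition groups: the first is
# serine-poor (LOR1-flavoured), the second serine-rich (LOR3-flavoured);
# realized serine percentages differ by ~15 points between groups
SERINE_POOR_WEIGHTS = (0.75, 0.10, 0.10, 0.05)
SERINE_RICH_WEIGHTS = (0.43, 0.42, 0.10, 0.05)


@pytest.fixture
def lor3_record():
    params = GeneratorParams(
        n_loops=10,
        loop_size_sampler=("uniform", 6, 12),
        index_style=IndexStyle.LOR3_LIKE,
        seed=42,
    )
    return generate_loricrin_protein(params)


@pytest.fixture
def lor1_record():
    params = GeneratorParams(
        n_loops=8,
        loop_size_sampler=("uniform", 8, 16),
        index_style=IndexStyle.LOR1_LIKE,
        seed=7,
    )
    return generate_loricrin_protein(params)
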