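import pytest
from hypothesis import settings

from softsample import SequenceRecord, generate_genome

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")


@pytest.fixture
def simple_record() -> SequenceRecord:
    return SequenceRecord("a", "ACGTACGTACGT")


@pytest.fixture
def genome_1kb() -> SequenceRecord:
    return generate_genome(1000, seed=42)


def write_lines(path, text: str) -> str:
    path.write_text(text)
    return str(path)
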