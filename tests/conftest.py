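import pytest
from hypothesis import HealthCheck, settings

# Deterministic property testing: same examples on every run.
settings.register_profile(
    "maskqc",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("maskqc")

from maskqc import FastqRecord  # noqa: E402


@pytest.fixture
def simple_record() -> FastqRecord:
    return FastqRecord("r1", "ACGT", [30, 10, 40, 2])


def make_records(n: int, length: int = 10, q: int = 30) -> list[FastqRecord]:
    return [
        FastqRecord(f"r{i}", "ACGT" * (length // 4) + "A" * (length % 4), [q] * length)
        for i in range(n)
    ]
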