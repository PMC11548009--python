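import pytest

from famefuel.profiles import FameProfile
from famefuel.registry import parse_shorthand

# The published five-component FAME profile of the AQYS21 isolate
# (mass % of total FAMEs); the pipeline's golden worked example.
AQYS21_ROWS = [
    ("Palmitic acid (C16:0)", 25.5),
    ("Stearic acid (C18:0)", 0.87),
    ("Oleic acid (C18:1 n-9)", 13.3),
    ("Linoleic acid (C18:2 n-6)", 5.98),
    ("α-linolenic acid (C18:3 n-3)", 54.39),
]


@pytest.fixture(scope="session")
def aqys21_profile() -> FameProfile:
    return FameProfile(
        components=[(parse_shorthand(label), pct) for label, pct in AQYS21_ROWS],
        source_id="AQYS21",
    )


@pytest.fixture()
def aqys21_csv(tmp_path):
    path = tmp_path / "aqys21.csv"
    lines = ["Component,Content (%)"]
    lines += [f"{label},{pct}" for label, pct in AQYS21_ROWS]
    lines += [
        "Total saturated fatty acids,26.37",
        "Total monounsaturated fatty acids,13.3",
        "Total polyunsaturated fatty acids,60.37",
    ]
    path.write_text("\n".join(lines))
    return path
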