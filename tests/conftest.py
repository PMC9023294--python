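import pandas as pd
import pytest

from phagepack import MsPeakSet


@pytest.fixture
def yera_peaks() -> MsPeakSet:
    """The published YerA41 ladder: three parents sharing the 346 core."""
    return MsPeakSet(
        parents=[918.0, 1102.0, 1286.0],
        fragments={
            918.0: [346.0, 572.0],
            1102.0: [346.0, 756.0],
            1286.0: [346.0, 940.0],
        },
    )


@pytest.fixture
def table1_row1() -> pd.DataFrame:
    """Peak-area table whose ratio-calibrated percentages are Table-1 row 1.

    Per-nucleoside responses differ; the equal-concentration standard run
    must cancel them.
    """
    rows = []
    for nuc, pct, response in [
        ("dA", 38.6, 1.7),
        ("dG", 21.0, 0.6),
        ("dC", 24.8, 1.1),
        ("T", 15.6, 0.9),
    ]:
        rows.append(
            {
                "nucleoside": nuc,
                "class": "deoxy",
                "sample_area": response * pct,
                "standard_area": response * 50.0,
            }
        )
    return pd.DataFrame(rows)
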