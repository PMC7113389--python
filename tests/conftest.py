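import numpy as np
import pandas as pd
import pytest

from regaze.textfeatures import Lexicon
from regaze.gaze import Fixation, InterestArea


@pytest.fixture
def toy_lexicon():
    return Lexicon({"cat": 10, "bat": 20, "rat": 5, "cot": 10, "cart": 7})


@pytest.fixture
def line_areas():
    """Two lines of two words each on one screen."""
    return [
        InterestArea("s1", 1, 1, 0, 0, 100, 30),
        InterestArea("s1", 1, 2, 110, 0, 220, 30),
        InterestArea("s1", 2, 1, 0, 60, 100, 90),
        InterestArea("s1", 2, 2, 110, 60, 220, 90),
    ]


def make_scanpath(durs_keys, pid="p1", session="first", sonnet="s1"):
    """Build an assigned sequence [(Fixation, key), ...] from (key, dur) pairs."""
    out = []
    for i, (key, dur) in enumerate(durs_keys, start=1):
        fix = Fixation(pid, session, sonnet, i, 5.0, 5.0, float(dur))
        out.append((fix, key))
    return out


@pytest.fixture
def small_long_table():
    """Minimal word x session long table for the mixed model."""
    rng = np.random.default_rng(0)
    rows = []
    for s in ("sA", "sB"):
        for w in range(1, 21):
            base = rng.normal(500, 80)
            for ses, shift in (("first", 0.0), ("last", -100.0)):
                rows.append({
                    "sonnet_id": s, "line_no": 1, "word_no": w,
                    "session": ses,
                    "trt": base + shift + rng.normal(0, 20),
                })
    return pd.DataFrame(rows)
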