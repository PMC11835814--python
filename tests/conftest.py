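from datetime import datetime, timedelta

import numpy as np
import pytest

from songseq.annotation_io import Bout, SyllableEvent

T0 = datetime(2024, 1, 8, 10, 0, 0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_events(gaps, file_id="f1", file_start=T0, singer="s1", label="a", dur=0.1):
    """Events with the given inter-event silent gaps (len(gaps)+1 events)."""
    events = []
    t = 0.0
    for i in range(len(gaps) + 1):
        events.append(SyllableEvent(label=label, onset=t, offset=t + dur,
                                    file_id=file_id, file_start=file_start,
                                    singer=singer))
        if i < len(gaps):
            t += dur + gaps[i]
    return events


def bout_from_labels(labels, file_id="f1", file_start=T0, singer="s1",
                     dur=0.1, gap=0.05):
    """A bout whose syllable sequence is the given label string/list."""
    events = []
    t = 0.0
    for lab in labels:
        events.append(SyllableEvent(label=lab, onset=t, offset=t + dur,
                                    file_id=file_id, file_start=file_start,
                                    singer=singer))
        t += dur + gap
    return Bout(events=events, bout_start=events[0].abs_onset)


def random_bouts(rng, n_bouts, alphabet="xabl", min_len=1, max_len=12):
    """Random label-sequence bouts for oracle comparisons."""
    out = []
    for i in range(n_bouts):
        n = int(rng.integers(min_len, max_len + 1))
        labels = [alphabet[k] for k in rng.integers(0, len(alphabet), size=n)]
        out.append(bout_from_labels(labels, file_id=f"f{i}",
                                    file_start=T0 + timedelta(seconds=30.0 * i)))
    return out
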