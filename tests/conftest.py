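import numpy as np
import pytest

from epivmd.preprocess import Epoch
from epivmd.synthetic_data import GenConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fs():
    return 256.0


@pytest.fixture
def tone_epoch(fs):
    """Pure 10 Hz sinusoid, 2 s."""
    t = np.arange(512) / fs
    return Epoch(np.sin(2 * np.pi * 10 * t), fs=fs, channel="FZCZ")


@pytest.fixture
def gen_config():
    return GenConfig(seed=0)


def write_minimal_edf(path, signals, labels, fs, phys_dim="uV"):
    """Write a one-record EDF file by hand (ASCII header + 16-bit LE ints).

    Kept in the test tree so EDF ingestion can be exercised without any
    binary fixture; the file is created at test time.
    """
    import struct

    n_sig = len(signals)
    n_samples = len(signals[0])
    duration = n_samples / fs
    phys_min, phys_max = -1000.0, 1000.0
    dig_min, dig_max = -32768, 32767

    def pad(text, width):
        s = str(text)[:width]
        return s + " " * (width - len(s))

    header = "".join(
        [
            pad("0", 8),
            pad("X X X X", 80),
            pad("synthetic test recording", 80),
            pad("01.01.20", 8),
            pad("00.00.00", 8),
            pad(256 + 256 * n_sig, 8),
            pad("", 44),
            pad("1", 8),                      # one data record
            pad(f"{duration:g}", 8),
            pad(n_sig, 4),
        ]
    )
    header += "".join(pad(lab, 16) for lab in labels)
    header += "".join(pad("EEG", 80) for _ in range(n_sig))
    header += "".join(pad(phys_dim, 8) for _ in range(n_sig))
    header += "".join(pad(f"{phys_min:g}", 8) for _ in range(n_sig))
    header += "".join(pad(f"{phys_max:g}", 8) for _ in range(n_sig))
    header += "".join(pad(dig_min, 8) for _ in range(n_sig))
    header += "".join(pad(dig_max, 8) for _ in range(n_sig))
    header += "".join(pad("", 80) for _ in range(n_sig))
    header += "".join(pad(n_samples, 8) for _ in range(n_sig))
    header += "".join(pad("", 32) for _ in range(n_sig))

    scale = (dig_max - dig_min) / (phys_max - phys_min)
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        for sig in signals:
            dig = np.clip(
                np.round((np.asarray(sig) - phys_min) * scale + dig_min),
                dig_min,
                dig_max,
            ).astype(int)
            fh.write(struct.pack(f"<{n_samples}h", *dig))
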