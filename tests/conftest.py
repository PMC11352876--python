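import numpy as np
import pytest

from szdetect import data


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_synth():
    """24 short synthetic records (12 per class), fast to process."""
    return data.synth_dataset(
        data.SynthConfig(n_per_class=12, n_samples=512, seizure_beta_gain=4.0, seed=7)
    )


@pytest.fixture
def sine_record():
    def make(freq, fs=data.BONN_FS, n=4097, amp=1.0):
        t = np.arange(n) / fs
        return data.EEGRecord(amp * np.sin(2 * np.pi * freq * t), fs=fs)

    return make


@pytest.fixture
def bonn_tree(tmp_path):
    """A miniature Bonn-style directory: sets D and E with 5 files each."""
    rng = np.random.default_rng(0)
    for set_name in ("D", "E"):
        set_dir = tmp_path / set_name
        set_dir.mkdir()
        for i in range(5):
            values = rng.integers(-200, 200, size=128)
            (set_dir / f"{set_name}{i:03d}.txt").write_text(
                "\n".join(str(v) for v in values) + "\n"
            )
    return tmp_path
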