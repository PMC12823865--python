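import numpy as np
import pytest

from epimatch import Recipient, StreamConfig, Supplier, generate_stream


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_recipient(id="r0", loc=(0, 0), dr="high", t=0, q=5, matched=0):
    return Recipient(id=id, loc=loc, dr=dr, request_time=t, q=q, matched_q=matched)


def make_supplier(id="s0", loc=(0, 0), sr=1, t=0, q=5, l=10, matched=0):
    return Supplier(id=id, loc=loc, sr=sr, request_time=t, q=q, l=l, matched_q=matched)


def random_instance(rng, n_recipients=6, n_suppliers=6, qmax=5, grid=10, lmax=12):
    """Small random matching instance for oracle-based property tests."""
    recipients = [
        make_recipient(
            id=f"r{i:02d}",
            loc=(int(rng.integers(0, grid)), int(rng.integers(0, grid))),
            dr=str(rng.choice(["high", "low"])),
            t=int(rng.integers(0, 5)),
            q=int(rng.integers(1, qmax + 1)),
        )
        for i in range(n_recipients)
    ]
    suppliers = [
        make_supplier(
            id=f"s{j:02d}",
            loc=(int(rng.integers(0, grid)), int(rng.integers(0, grid))),
            sr=int(rng.integers(1, 4)),
            t=int(rng.integers(0, 5)),
            q=int(rng.integers(1, qmax + 1)),
            l=int(rng.integers(1, lmax)),
        )
        for j in range(n_suppliers)
    ]
    return recipients, suppliers


@pytest.fixture(scope="session")
def small_stream():
    """A scaled-down arrival stream for end-to-end window tests."""
    cfg = StreamConfig(T=30, n_recipients=200, n_suppliers=120, seed=7)
    return generate_stream(cfg), cfg


@pytest.fixture(scope="session")
def default_stream():
    """The full default experimental stream (seed 42)."""
    cfg = StreamConfig(seed=42)
    return generate_stream(cfg), cfg
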