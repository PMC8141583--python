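import numpy as np
import pytest

from aestherl.engine import Trajectory


@pytest.fixture
def make_trajectory():
    """Factory for synthetic trajectories with explicit per-iteration series."""

    def _make(w, delta=None, u=None, r_star=None, m_bar=None, thin=1, tail_stored=None):
        w = np.atleast_2d(np.asarray(w, dtype=float))
        n = len(w)
        delta = np.zeros(n) if delta is None else np.asarray(delta, dtype=float)
        u = np.full((n, 2), 0.5) if u is None else np.asarray(u, dtype=float)
        r_star = np.zeros(n) if r_star is None else np.asarray(r_star, dtype=float)
        m_bar = np.ones(n) if m_bar is None else np.asarray(m_bar, dtype=float)
        return Trajectory(
            t=np.arange(1, n + 1, dtype=np.int64),
            w=w,
            delta=delta,
            u=u,
            r_star=r_star,
            m_bar=m_bar,
            condition_id=0,
            seed=0,
            n_iterations=n,
            thin=thin,
            tail_stored=n if tail_stored is None else tail_stored,
        )

    return _make


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260919)
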