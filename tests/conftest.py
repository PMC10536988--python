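import numpy as np
import pytest

from trajclust.similarity import DistanceMatrix


def make_distance_matrix(points: np.ndarray, metric: str = "l2") -> DistanceMatrix:
    """Distance matrix from 1-D or 2-D point coordinates (test helper)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] == 1:
        pts = pts.T
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(
        values=d, metric=metric,
        traj_ids=[f"t{i}" for i in range(pts.shape[0])],
    )


@pytest.fixture
def two_frame_xyz(tmp_path):
    """Minimal 2-frame, 2-atom XYZ file: H at (0,0,0) and (0,0,1)."""
    p = tmp_path / "two.xyz"
    p.write_text(
        "2\nframe 0\nH 0 0 0\nH 0 0 1\n"
        "2\nframe 1\nH 0 0 0\nH 0 0 1.5\n"
    )
    return p


@pytest.fixture(scope="session")
def small_spec():
    """A scaled-down synthetic spec for fast unit tests."""
    from dataclasses import replace
    from trajclust.synthetic import default_spec

    return replace(default_spec(seed=11), n_traj=24, n_time=60)


@pytest.fixture(scope="session")
def small_pipeline(small_spec):
    """Generated features + normalized matrix + L2 distances + truth."""
    from trajclust.features import minmax_normalize
    from trajclust.similarity import pairwise_distance_matrix
    from trajclust.synthetic import generate

    fm, labels, pops = generate(small_spec)
    nfm = minmax_normalize(fm)
    dm = pairwise_distance_matrix(nfm, "l2")
    return {"fm": fm, "nfm": nfm, "dm": dm, "labels": labels, "pops": pops}
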