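import numpy as np
import pytest

from mitonet.elements import classify_and_merge, extract_clusters, split_four_way
from mitonet.skeleton import SkeletonGraph

PX_UM = 1.0 / 15.0


def clusters_from_skeleton(arr: np.ndarray, pixel_size_um: float = PX_UM, split: bool = True):
    """Classify a hand-drawn boolean skeleton into clusters."""
    graph = classify_and_merge(SkeletonGraph(np.asarray(arr, bool), pixel_size_um))
    if split:
        split_four_way(graph)
    return extract_clusters(graph), graph


def draw_segment(arr, r0, c0, dr, dc, n):
    """Draw n pixels from (r0, c0) stepping by (dr, dc); returns end pixel."""
    r, c = r0, c0
    for _ in range(n):
        arr[r, c] = True
        r += dr
        c += dc
    return r - dr, c - dc


@pytest.fixture
def straight_line():
    """Horizontal 31-px line: 1 tubule, 2 ends (30 px = 2 um)."""
    arr = np.zeros((9, 41), bool)
    arr[4, 5:36] = True
    return arr


@pytest.fixture
def t_cluster():
    """Degree-3 junction with arms of 45, 45 and 60 px (3, 3, 4 um)."""
    arr = np.zeros((121, 121), bool)
    draw_segment(arr, 59, 60, -1, 0, 46)  # up, 45 steps
    draw_segment(arr, 60, 61, 0, 1, 45)  # right, 45 steps from centre px
    draw_segment(arr, 61, 60, 1, 0, 60)  # down, 60 steps
    arr[60, 60] = True
    return arr


@pytest.fixture
def h_cluster():
    """H-shape: 2 junctions, 5 tubules, 4 ends."""
    arr = np.zeros((41, 41), bool)
    arr[5:36, 10] = True
    arr[5:36, 30] = True
    arr[20, 11:30] = True
    return arr


@pytest.fixture
def lollipop():
    """Square ring with a tail: junction attached twice to the ring tubule,
    third attachment leading to an end (a donut)."""
    arr = np.zeros((45, 45), bool)
    arr[10, 10:31] = True
    arr[30, 10:31] = True
    arr[10:31, 10] = True
    arr[10:31, 30] = True
    arr[31:42, 20] = True  # tail from the bottom edge
    return arr


@pytest.fixture
def theta_cluster():
    """Square ring with an internal chord: two junctions, no free end."""
    arr = np.zeros((45, 45), bool)
    arr[10, 10:31] = True
    arr[30, 10:31] = True
    arr[10:31, 10] = True
    arr[10:31, 30] = True
    arr[11:30, 20] = True  # chord
    return arr
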