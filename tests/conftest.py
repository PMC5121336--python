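import numpy as np
import pytest
from hypothesis import settings

from ldlscreen.screen import PLATE_ROWS, Plate, Well

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_plate(
    sample_intensities,
    neg=(100.0, 101.0, 99.0),
    pos=(20.0, 21.0, 19.0),
    plate_id="P001",
    replicate=1,
    cell_counts=None,
    dead_fractions=None,
):
    """Build a valid plate from raw intensity vectors (test helper)."""
    labels = [(r, c) for r in PLATE_ROWS for c in range(1, 25)]
    wells = []
    i = 0
    for v in neg:
        r, c = labels[i]
        wells.append(Well(plate_id, r, c, "neg_control", float(v), 300, 0.05))
        i += 1
    for v in pos:
        r, c = labels[i]
        wells.append(Well(plate_id, r, c, "pos_control", float(v), 300, 0.05))
        i += 1
    for j, v in enumerate(sample_intensities):
        r, c = labels[i]
        cc = 300 if cell_counts is None else cell_counts[j]
        df = 0.05 if dead_fractions is None else dead_fractions[j]
        wells.append(
            Well(plate_id, r, c, "sample", float(v), cc, df, gene_id=f"G{j:04d}", sirna_id=f"s{j}")
        )
        i += 1
    return Plate(plate_id, wells, replicate_id=replicate)


@pytest.fixture(scope="session")
def tirf_movie_pair():
    """One synthetic control movie plus its ground-truth fusion list."""
    from ldlscreen.simulate import TirfSimSpec, gen_tirf_movie

    return gen_tirf_movie(TirfSimSpec(seed=11))


def match_events(events, truth, frame_tol=2, dist_tol=3.0):
    """Greedy one-to-one matching of detected events to planted fusions."""
    det = [(e.fusion_frame, e.position[0], e.position[1]) for e in events]
    used = set()
    tp = 0
    for _, row in truth.iterrows():
        for i, (f, r, c) in enumerate(det):
            if i in used:
                continue
            if abs(f - row.fusion_frame) <= frame_tol and np.hypot(
                r - row.row, c - row.col
            ) <= dist_tol:
                used.add(i)
                tp += 1
                break
    return tp
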