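import numpy as np
import pytest

from svpools.model import (
    RECYCLED,
    RESTING,
    ActiveZoneTrace,
    SynapseSection,
    VesicleAnnotation,
)


def build_section(
    centers,
    labels,
    az=((-100.0, 0.0), (100.0, 0.0)),
    sid="s1",
    condition="control",
    radius=20.0,
    boundary=None,
    az_center=None,
):
    """Assemble a SynapseSection from bare arrays (no validation shortcuts)."""
    vesicles = tuple(
        VesicleAnnotation(id=f"{sid}:v{i}", x=float(x), y=float(y), label=lab, radius=radius)
        for i, ((x, y), lab) in enumerate(zip(centers, labels))
    )
    azs = (ActiveZoneTrace(points=tuple(az), center=az_center),)
    return SynapseSection(
        id=sid,
        condition=condition,
        vesicles=vesicles,
        active_zones=azs,
        boundary=boundary,
    )


def random_section(rng, n=25, p=0.4, sid="rand", box=((-300, 20), (300, 500)),
                   az=((-100.0, 0.0), (100.0, 0.0))):
    """Random unlabeled-geometry section with iid Bernoulli(p) labels."""
    (x0, y0), (x1, y1) = box
    centers = np.column_stack(
        [rng.uniform(x0, x1, n), rng.uniform(y0, y1, n)]
    )
    labels = [RECYCLED if rng.random() < p else RESTING for _ in range(n)]
    if RECYCLED not in labels:
        labels[0] = RECYCLED
    return build_section(centers, labels, az=az, sid=sid)


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)
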