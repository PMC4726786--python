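import numpy as np
import pytest

from blkit import SimConfig, simulate
from blkit.format import BrainLinerFile, DataGroup, FileHeader, GroupProps


@pytest.fixture(scope="session")
def default_session():
    """One default synthetic session shared across tests (seed 1)."""
    return simulate(SimConfig())


def random_valid_file(rng: np.random.Generator) -> BrainLinerFile:
    """Draw a random file model satisfying every format invariant."""
    header = FileHeader(
        description=rng.choice(["", "a block-design session", "resting state"]),
        attributes={"species": str(rng.choice(["rat", "human", "macaque"]))},
    )
    groups = []
    for gi in range(rng.integers(0, 4)):
        name = f"group{gi}"
        has_data = rng.random() < 0.7
        has_spans = rng.random() < 0.5
        has_stamps = rng.random() < 0.4
        if not (has_data or has_spans or has_stamps):
            has_data = True

        data = spans = stamps = labels = None
        sampling_rate = None
        channel_names = None
        roi, stats = {}, {}
        if has_data:
            s, c = int(rng.integers(4, 40)), int(rng.integers(1, 4))
            data = rng.standard_normal((s, c))
            sampling_rate = float(rng.choice([100.0, 1000.0]))
            if rng.random() < 0.5:
                channel_names = [f"ch{j}" for j in range(c)]
            if rng.random() < 0.3:
                roi = {"mask": (rng.random(data.shape) > 0.5).astype(np.float64)}
            if rng.random() < 0.3:
                stats = {"variance": rng.random(data.shape)}
        if has_spans:
            n = int(rng.integers(1, 6))
            starts = np.sort(rng.random(n) * 10)
            spans = np.column_stack([starts, starts + 0.1 + rng.random(n)])
            if rng.random() < 0.7:
                labels = [str(rng.choice(["A", "B", "rest"])) for _ in range(n)]
        if has_stamps:
            stamps = np.sort(rng.random(int(rng.integers(1, 10))) * 10)

        extra = {}
        if rng.random() < 0.5:
            extra["myCustomNote"] = "free-form annotation"
        if rng.random() < 0.3:
            extra["gainFactor"] = float(rng.random())

        groups.append(
            DataGroup(
                name=name,
                props=GroupProps(
                    title=f"title {gi}",
                    type=str(rng.choice(["ECoG", "EEG", "stimulus", "physicalMovement"])),
                    sampling_rate=sampling_rate,
                    channel_names=channel_names,
                    roi=roi,
                    stats=stats,
                    preprocessing="bandpassed" if rng.random() < 0.3 else None,
                    extra=extra,
                ),
                data=data,
                timespans=spans,
                labels=labels,
                timestamps=stamps,
            )
        )
    return BrainLinerFile(header=header, groups=groups)
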