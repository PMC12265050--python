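import numpy as np
import pytest

from sporetrack import SimulationConfig, simulate_trajectories, trajectories_to_dataframe
from sporetrack.tracking import Trajectory, trajectories_from_dataframe, trajectory_filter


def simulate_filtered_tracks(**kwargs) -> list[Trajectory]:
    """Simulate ground-truth tracks and return them as filtered Trajectories."""
    cfg = SimulationConfig(**kwargs)
    trajs = simulate_trajectories(cfg)
    tracks = trajectories_from_dataframe(
        trajectories_to_dataframe(trajs), frame_interval=cfg.frame_interval)
    return trajectory_filter(tracks)


def ground_truth_classes(**kwargs) -> tuple[list[Trajectory], np.ndarray]:
    """Filtered tracks plus the aligned true-class array."""
    cfg = SimulationConfig(**kwargs)
    trajs = simulate_trajectories(cfg)
    classes = np.array([t.true_class for t in trajs])
    tracks = trajectory_filter(trajectories_from_dataframe(
        trajectories_to_dataframe(trajs), frame_interval=cfg.frame_interval))
    assert len(tracks) == len(trajs)
    return tracks, classes


@pytest.fixture(scope="session")
def spore_like_chromatogram_spec():
    """A spore-like UPLC profile: anhydro species carry 93% of total area."""
    from sporetrack import ChromPeakSpec, ChromatogramSpec
    peaks = [
        ChromPeakSpec("M4", 5.0, 0.06, 0.04),
        ChromPeakSpec("D44", 8.0, 0.06, 0.03),
        ChromPeakSpec("M4Anh", 12.0, 0.06, 0.30),
        ChromPeakSpec("D44Anh", 15.0, 0.06, 0.35),
        ChromPeakSpec("T444Anh", 18.5, 0.06, 0.28),
    ]
    anh = sum(p.area for p in peaks if "Anh" in p.species_label)
    assert abs(anh / sum(p.area for p in peaks) - 0.93) < 1e-12
    return ChromatogramSpec(peaks=peaks, baseline_offset=0.02,
                            baseline_slope=0.001, sample_id="spore")
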