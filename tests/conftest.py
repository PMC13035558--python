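import numpy as np
import pytest

from endoview.discovery import DiscoveryConfig, apply_label_map, cluster_descriptors
from endoview.synthetic import SyntheticConfig, generate


@pytest.fixture(scope="session")
def default_video():
    """One default-sized synthetic procedure shared across tests."""
    return generate(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def recovered_model(default_video):
    """K-means model recovered from the default video, labeled by matching
    each recovered centroid to its nearest planted centroid (the automated
    stand-in for the human cluster-labeling step)."""
    from scipy.spatial.distance import cdist

    video = default_video
    emitted = np.unique(video.emitting_cluster)
    km = cluster_descriptors(video.dm, DiscoveryConfig(k=len(emitted), seed=1))
    nearest = cdist(km.centroids, video.true_model.centroids).argmin(axis=1)
    label_map = {
        i: video.true_model.cluster_label[int(m)] for i, m in enumerate(nearest)
    }
    return apply_label_map(km, label_map, video.true_model.hierarchy)
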