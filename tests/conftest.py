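import numpy as np
import pandas as pd
import pytest

from restdyn.io import ParcellatedSeries, ParcelMetadata

EIGHT_NETWORKS = [
    "visual",
    "somatomotor",
    "dorsal_attention",
    "ventral_attention",
    "limbic",
    "temporal",
    "frontoparietal",
    "default_mode",
]


def make_series(values, tr=2.0, subject="s1", visit="V1", labels=None):
    values = np.asarray(values, dtype=float)
    if labels is None:
        labels = [f"r{i}" for i in range(values.shape[0])]
    return ParcellatedSeries(
        subject_id=subject,
        visit_id=visit,
        tr_seconds=tr,
        values=values,
        region_labels=labels,
    )


def make_metadata(networks_regions, seeds=()):
    """networks_regions: dict network -> list of region labels."""
    rows = []
    for net, labs in networks_regions.items():
        for lab in labs:
            rows.append(
                {"region_label": lab, "role": "cortical", "network": net,
                 "hemisphere": "L"}
            )
    for seed in seeds:
        rows.append(
            {"region_label": seed, "role": "subcortical_seed", "network": seed,
             "hemisphere": "bilateral"}
        )
    return ParcelMetadata(pd.DataFrame(rows))


@pytest.fixture
def eight_network_metadata():
    """8 networks x 5 regions + the three subcortical seeds."""
    nets = {net: [f"{net}_{k}" for k in range(5)] for net in EIGHT_NETWORKS}
    return make_metadata(nets, seeds=("NBM", "LC", "BG"))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
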