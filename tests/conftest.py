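import itertools

import numpy as np
import pytest

from pcmbench.datasets import ActivityRecord, PCMDataset, TargetEntry
from pcmbench.tables import NATURAL_AAS, DescriptorTable


def toy_table(values_by_aa, name="toy", fill=None):
    """A 1-component table with chosen values; remaining AAs get `fill`
    (defaults to the mean of the chosen values, keeping the range intact)."""
    chosen = dict(values_by_aa)
    if fill is None:
        fill = float(np.mean(list(chosen.values())))
    values = {aa: [chosen.get(aa, fill)] for aa in NATURAL_AAS}
    return DescriptorTable(name=name, kind="continuous", values=values,
                           component_labels=("C1",))


@pytest.fixture
def toy_1comp():
    return toy_table({"A": 1.0, "C": 2.0, "D": 3.0, "E": 4.0})


def grid_dataset(n_compounds, n_targets, n_records, residue_len=3, value=5.0,
                 name="grid", task="regression"):
    """A dataset whose activity table is the first n_records cells of the
    compound x target grid (arithmetic fixtures for completeness checks)."""
    compounds = [(f"c{i}", "bits:0101") for i in range(n_compounds)]
    targets = [TargetEntry(f"t{j}", "A" * residue_len) for j in range(n_targets)]
    cells = itertools.product(range(n_compounds), range(n_targets))
    activities = []
    for i, j in itertools.islice(cells, n_records):
        if task == "regression":
            activities.append(ActivityRecord(f"c{i}", f"t{j}", value=value))
        else:
            activities.append(ActivityRecord(f"c{i}", f"t{j}",
                                             class_label="active"))
    return PCMDataset(name=name, task=task, compounds=compounds,
                      targets=targets, activities=activities)
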