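import networkx as nx
import numpy as np
import pandas as pd
import pytest

from inflamnet import DynaNetwork, MediatorPanel, TimeWindow


def make_panel(
    values: np.ndarray,
    mediators: list[str] | None = None,
    times: list[float] | None = None,
    group: str = "g",
    time_unit: str = "day",
) -> MediatorPanel:
    """Panel from a (subjects, times, mediators) array; NaN = missing."""
    values = np.asarray(values, dtype=float)
    n_subj, n_times, n_med = values.shape
    mediators = mediators or [f"M{k}" for k in range(n_med)]
    times = times or list(range(n_times))
    rows = [
        (f"s{si}", times[ti], mediators[mi], values[si, ti, mi])
        for si in range(n_subj)
        for ti in range(n_times)
        for mi in range(n_med)
    ]
    data = pd.DataFrame(rows, columns=["subject", "time", "mediator", "value"])
    groups = {f"s{si}": group for si in range(n_subj)}
    return MediatorPanel(data, groups, mediators, time_unit)


def net_from_edges(
    mediators: list[str],
    edges: list[tuple[str, str, str]],
    label: str = "w",
    start: float = 0.0,
    end: float = 1.0,
) -> DynaNetwork:
    """Hand-built network from (a, b, sign) triples for formula tests."""
    g = nx.Graph()
    g.add_nodes_from(mediators)
    for a, b, sign in edges:
        g.add_edge(a, b, r=1.0 if sign == "+" else -1.0, sign=sign, n_pairs=5)
    return DynaNetwork(TimeWindow(label, start, end), list(mediators), g)


@pytest.fixture
def window01() -> TimeWindow:
    return TimeWindow("d0-d1", 0, 1)


@pytest.fixture
def long_csv(tmp_path):
    """2 subjects x 2 times x 2 mediators, long layout."""
    path = tmp_path / "panel.csv"
    rows = ["subject,time,mediator,value,group"]
    for s in ("a", "b"):
        for t in (0, 1):
            for m, v in (("IL-6", 10.0), ("TNF-a", 20.0)):
                rows.append(f"{s},{t},{m},{v},ctrl")
    path.write_text("\n".join(rows) + "\n")
    return path
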