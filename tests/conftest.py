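import numpy as np
import pytest

from emsrank.enumeration import Configuration
from emsrank.system_model import Fleet, SystemDescription, load_fixture


@pytest.fixture(scope="session")
def bauru():
    return load_fixture("bauru")


@pytest.fixture(scope="session")
def ribeirao():
    return load_fixture("ribeirao_preto")


def make_single_group_system(n: int, offered_load: float, service_time: float = 30.0,
                             queue_capacity: int = 0) -> SystemDescription:
    """A degenerate 2-atom system with one basic group of n servers in atom 1
    and regular calls only, so the chain collapses to an M/M/n loss or
    finite-queue system with offered load ``offered_load`` erlangs."""
    lam = offered_load / service_time
    return SystemDescription(
        atoms=("Z1", "Z2"),
        arrival_rate={(0, "regular"): lam},
        travel_time=np.full((2, 2), 10.0),
        service_time={"BSU": service_time},
        fleets=(Fleet("BSU", n),),
        queue_capacity=queue_capacity,
    )


def single_group_config(n: int) -> Configuration:
    return Configuration(1, {"BSU": (n, 0)})


def make_two_atom_system(queue_capacity: int = 3, with_asu: bool = False,
                         util: float = 0.5) -> SystemDescription:
    """A small asymmetric 2-atom toy used for oracle cross-checks."""
    tt = np.array([[6.0, 12.0], [11.0, 8.0]])
    service = {"BSU": 30.0}
    fleets = [Fleet("BSU", 2)]
    if with_asu:
        service["ASU"] = 40.0
        fleets.append(Fleet("ASU", 1, dedicated=True, fixed_atoms=(1, 0)))
    n = 2 + int(with_asu)
    lam_total = util * n / 32.0
    return SystemDescription(
        atoms=("Z1", "Z2"),
        arrival_rate={
            (0, "serious"): 0.12 * lam_total,
            (0, "regular"): 0.48 * lam_total,
            (1, "serious"): 0.08 * lam_total,
            (1, "regular"): 0.32 * lam_total,
        },
        travel_time=tt,
        service_time=service,
        fleets=tuple(fleets),
        queue_capacity=queue_capacity,
    )
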