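"""Hypothesis space of thalamo-cortical network architectures.

The network has six regions (V1, SPC, thalamus, basal ganglia, dACC, dPFC)
in a fixed canonical order that defines row/column semantics for every
matrix in the package.  Eight hypothesis-neutral intrinsic connections are
fixed across the space; four fronto-thalamic connections are permuted over
three states (absent / present / present-and-modulated by both attention
conditions) and the dPFC->BG connection over two (absent /
present-and-modulated), giving 3**4 * 2 = 162 candidate architectures.

Matrix convention: ``a[target, source]`` — the entry in row *i*, column *j*
is the influence of region *j* on region *i* (dx_i/dt picks up a_ij * x_j).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

REGIONS: tuple[str, ...] = ("V1", "SPC", "Thal", "BG", "dACC", "dPFC")
REGION_INDEX: dict[str, int] = {name: i for i, name in enumerate(REGIONS)}
N_REGIONS = len(REGIONS)
N_INPUTS = 2  # low-demand and high-demand condition inputs
CONDITIONS: tuple[str, str] = ("low", "high")


class ConnState(str, Enum):
    """State of a permuted connection within one candidate architecture."""

    ABSENT = "absent"
    PRESENT = "present"
    PRESENT_MODULATED = "present_modulated"


#: enumeration order within a permuted slot (lexicographic over models)
STATE_ORDER_3 = (ConnState.ABSENT, ConnState.PRESENT, ConnState.PRESENT_MODULATED)
STATE_ORDER_2 = (ConnState.ABSENT, ConnState.PRESENT_MODULATED)

Connection = tuple[str, str]  # (source, target)


def connection_label(conn: Connection) -> str:
    return f"{conn[0]}->{conn[1]}"


def parse_connection(label: str) -> Connection:
    src, _, dst = label.partition("->")
    if src not in REGION_INDEX or dst not in REGION_INDEX:
        raise ValueError(f"unknown region in connection label {label!r}")
    return (src, dst)


@dataclass(frozen=True)
class NetworkTemplate:
    """Fixed skeleton plus the permuted slots that define the model space."""

    fixed_connections: tuple[Connection, ...] = (
        ("V1", "SPC"),
        ("V1", "Thal"),
        ("SPC", "Thal"),
        ("SPC", "BG"),
        ("Thal", "BG"),
        ("BG", "Thal"),
        ("BG", "dPFC"),
        ("dACC", "BG"),
    )
    permuted3: tuple[Connection, ...] = (
        ("Thal", "dPFC"),
        ("dPFC", "Thal"),
        ("Thal", "dACC"),
        ("dACC", "Thal"),
    )
    permuted2: tuple[Connection, ...] = (("dPFC", "BG"),)
    driving_targets: tuple[str, ...] = ("V1",)

    def __post_init__(self) -> None:
        for conn in self.all_connections():
            src, dst = conn
            if src not in REGION_INDEX or dst not in REGION_INDEX:
                raise ValueError(f"unknown region in connection {conn}")
            if src == dst:
                raise ValueError(f"self-loop not allowed: {conn}")
        fixed = set(self.fixed_connections)
        permuted = set(self.permuted3) | set(self.permuted2)
        if fixed & permuted:
            raise ValueError("fixed and permuted connection lists overlap")
        if len(fixed) != len(self.fixed_connections):
            raise ValueError("duplicate fixed connections")
        for t in self.driving_targets:
            if t not in REGION_INDEX:
                raise ValueError(f"unknown driving target {t!r}")

    def all_connections(self) -> tuple[Connection, ...]:
        return self.fixed_connections + self.permuted_connections()

    def permuted_connections(self) -> tuple[Connection, ...]:
        return self.permuted3 + self.permuted2

    @property
    def n_models(self) -> int:
        return 3 ** len(self.permuted3) * 2 ** len(self.permuted2)


def default_template() -> NetworkTemplate:
    """The study's 13-pathway template: 8 fixed + 4 tri-state + 1 bi-state."""
    return NetworkTemplate()


@dataclass(frozen=True)
class ModelSpec:
    """One candidate architecture: a state for every permuted connection."""

    model_id: int
    states: dict[Connection, ConnState] = field(hash=False)

    def to_json_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "states": {connection_label(c): s.value for c, s in self.states.items()},
        }


@dataclass(frozen=True)
class MaskSet:
    """Binary masks over A, B (per condition) and C for one architecture."""

    a_mask: np.ndarray
    b_mask_low: np.ndarray
    b_mask_high: np.ndarray
    c_mask: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diag(self.a_mask)):
            raise ValueError("a_mask diagonal must be zero (self-decay is separate)")
        for b in (self.b_mask_low, self.b_mask_high):
            if np.any(b > self.a_mask):
                raise ValueError("modulation mask must be a subset of a_mask")

    @property
    def n_free(self) -> int:
        return int(
            self.a_mask.sum()
            + self.b_mask_low.sum()
            + self.b_mask_high.sum()
            + self.c_mask.sum()
        )


def enumerate_models(template: NetworkTemplate) -> list[ModelSpec]:
    """All architectures in deterministic lexicographic order.

    Tri-state slots vary in ``permuted3`` order with ABSENT < PRESENT <
    PRESENT_MODULATED, then the bi-state slot; ``model_id`` is the position.
    """
    slots = [STATE_ORDER_3] * len(template.permuted3) + [STATE_ORDER_2] * len(
        template.permuted2
    )
    conns = template.permuted_connections()
    specs = []
    for model_id, combo in enumerate(itertools.product(*slots)):
        specs.append(ModelSpec(model_id=model_id, states=dict(zip(conns, combo))))
    return specs


def masks(spec: ModelSpec, template: NetworkTemplate) -> MaskSet:
    """Binary masks for one architecture.

    A carries every fixed connection plus permuted connections that are
    present; B carries only modulated connections, identically for both
    attention conditions; C drives the template's driving targets with both
    condition inputs.
    """
    if set(spec.states) != set(template.permuted_connections()):
        raise ValueError("model states do not match the template's permuted slots")
    a = np.zeros((N_REGIONS, N_REGIONS), dtype=np.int8)
    b = np.zeros((N_REGIONS, N_REGIONS), dtype=np.int8)
    for src, dst in template.fixed_connections:
        a[REGION_INDEX[dst], REGION_INDEX[src]] = 1
    for conn, state in spec.states.items():
        src, dst = conn
        if state in (ConnState.PRESENT, ConnState.PRESENT_MODULATED):
            a[REGION_INDEX[dst], REGION_INDEX[src]] = 1
        if state is ConnState.PRESENT_MODULATED:
            b[REGION_INDEX[dst], REGION_INDEX[src]] = 1
    c = np.zeros((N_REGIONS, N_INPUTS), dtype=np.int8)
    for t in template.driving_targets:
        c[REGION_INDEX[t], :] = 1
    return MaskSet(a_mask=a, b_mask_low=b.copy(), b_mask_high=b.copy(), c_mask=c)


def full_model(template: NetworkTemplate) -> ModelSpec:
    """The saturated architecture: every permuted connection modulated."""
    specs = enumerate_models(template)
    return specs[-1]


def write_model_space(specs: list[ModelSpec], path) -> None:
    with open(path, "w") as fh:
        json.dump([s.to_json_dict() for s in specs], fh, indent=1)


def read_model_space(path) -> list[ModelSpec]:
    with open(path) as fh:
        raw = json.load(fh)
    return [
        ModelSpec(
            model_id=entry["model_id"],
            states={
                parse_connection(lbl): ConnState(v)
                for lbl, v in entry["states"].items()
            },
        )
        for entry in raw
    ]
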