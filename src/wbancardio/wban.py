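"""Tier-1/tier-2 body-area-network simulation.

Tier 1 (sensor nodes -> hub): each record is priority-tagged (``"00"`` critical
when any vital breaches its screening threshold, ``"01"`` otherwise), its
payload is encrypted under the hub's symmetric key, and packets are placed in
a TDMA frame with critical packets in the earliest slots (FIFO within a
priority class).

Tier 2 (hub -> base station): candidate channels carry Gaussian noise; the
stability statistic of a channel is the mean square of ``2a`` noise samples
(``a`` = time-bandwidth product), so for unit noise it concentrates at 1 by
chi-square concentration. Channel choice minimizes a weighted cost of noise
energy and failed-transmission fraction via the IDOX optimizer over the
integer channel index.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import aes
from .data import ATTRIBUTES, label_record
from .idox import IDOX, IDOXConfig, SearchSpace, decode_integer

PRIORITY_CRITICAL = "00"
PRIORITY_NORMAL = "01"


class CapacityError(RuntimeError):
    """More packets than TDMA slots; the caller must open a new frame."""


@dataclass
class Packet:
    payload: bytes
    priority: str
    source: int
    slot: int | None = None

    def __post_init__(self) -> None:
        if self.priority not in (PRIORITY_CRITICAL, PRIORITY_NORMAL):
            raise ValueError(f"priority must be '00' or '01', got {self.priority!r}")


@dataclass
class TDMAFrame:
    w: int
    assignments: dict = field(default_factory=dict)  # slot -> Packet

    def __post_init__(self) -> None:
        if self.w < 1:
            raise ValueError("frame must have at least one slot")

    @property
    def packets(self) -> list[Packet]:
        return [self.assignments[s] for s in sorted(self.assignments)]


@dataclass
class Channel:
    id: int
    noise_scale: float = 1.0
    a: int = 100
    success_prob: float = 1.0
    idle: bool = True

    def __post_init__(self) -> None:
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")
        if self.a < 1:
            raise ValueError("time-bandwidth product a must be >= 1")
        if not 0.0 <= self.success_prob <= 1.0:
            raise ValueError("success_prob must lie in [0, 1]")


@dataclass
class HubKey:
    hub_id: int
    key: bytes

    def __post_init__(self) -> None:
        if len(self.key) != aes.KEY_LEN:
            raise ValueError(f"key must be {aes.KEY_LEN} bytes for the configured cipher")


def classify_priority(record) -> str:
    """``"00"`` (critical) iff any screening threshold is breached, else ``"01"``.

    Accepts a VitalRecord, a mapping, or a pandas row with the three vitals.
    """
    get = record.get if hasattr(record, "get") else lambda k: getattr(record, k)
    vals = {a: float(get(a)) for a in ATTRIBUTES}
    return PRIORITY_CRITICAL if label_record(**vals, rule="any") else PRIORITY_NORMAL


encrypt_payload = aes.encrypt_payload
decrypt_payload = aes.decrypt_payload


def schedule_tdma(packets: list[Packet], w: int) -> TDMAFrame:
    """Assign packets to slots: criticals first, FIFO within each class."""
    if len(packets) > w:
        raise CapacityError(f"{len(packets)} packets exceed frame capacity w={w}")
    frame = TDMAFrame(w=max(w, 1))
    ordered = sorted(packets, key=lambda p: p.priority)  # stable: "00" < "01"
    for slot, pkt in enumerate(ordered):
        pkt.slot = slot
        frame.assignments[slot] = pkt
    return frame


def channel_stability(channel: Channel, rng: np.random.Generator) -> float:
    """Noise-energy statistic: mean of 2a squared Gaussian samples."""
    xi = rng.normal(0.0, channel.noise_scale, size=2 * channel.a)
    return float(np.mean(xi * xi))


def channel_fitness(
    channel: Channel,
    n_trials: int = 100,
    weights: tuple[float, float] = (0.5, 0.5),
    rng: np.random.Generator | None = None,
) -> float:
    """Cost = w1 * stability + w2 * failed-transmission fraction; lower is better."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    w1, w2 = weights
    if w1 < 0 or w2 < 0 or abs(w1 + w2 - 1.0) > 1e-9:
        raise ValueError("weights must be non-negative and sum to 1")
    rng = rng or np.random.default_rng()
    ds = channel_stability(channel, rng)
    successes = rng.random(n_trials) < channel.success_prob
    return float(w1 * ds + w2 * (1.0 - successes.mean()))


def expected_channel_fitness(
    channel: Channel, weights: tuple[float, float] = (0.5, 0.5)
) -> float:
    """Closed-form expectation of :func:`channel_fitness` (exhaustive oracle)."""
    w1, w2 = weights
    return float(w1 * channel.noise_scale**2 + w2 * (1.0 - channel.success_prob))


def select_channel(
    channels: list[Channel],
    idox_config: IDOXConfig | None = None,
    n_trials: int = 200,
    weights: tuple[float, float] = (0.5, 0.5),
    seed: int = 0,
) -> int:
    """Pick the idle channel with minimal sampled cost via IDOX integer search.

    Each channel's cost is sampled once (memoized) from a per-channel seeded
    stream, so the objective seen by the optimizer is deterministic within a
    call. Returns the chosen channel's id.
    """
    idle = [c for c in channels if c.idle]
    if not idle:
        raise ValueError("no idle channel available")
    if len(idle) == 1:
        return idle[0].id
    root = np.random.SeedSequence(seed)
    streams = [np.random.default_rng(s) for s in root.spawn(len(idle))]
    cache: dict[int, float] = {}

    def cost_of(i: int) -> float:
        if i not in cache:
            cache[i] = channel_fitness(idle[i], n_trials, weights, streams[i])
        return cache[i]

    cfg = idox_config or IDOXConfig(population_size=5, max_iterations=5, seed=seed)
    space = SearchSpace(1, 0.0, float(len(idle) - 1), encoding="integer")
    result = IDOX(space, cfg).optimize(
        lambda pos: cost_of(int(decode_integer(pos, 0, len(idle) - 1)[0]))
    )
    best = int(decode_integer(result.best_position, 0, len(idle) - 1)[0])
    return idle[best].id


def simulate_transmission(
    df: pd.DataFrame,
    channels: list[Channel] | None = None,
    hub_key: HubKey | None = None,
    frame_size: int | None = None,
    drop_on_failure: bool = False,
    seed: int = 0,
    idox_config: IDOXConfig | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Run the aggregation/transmission tier over a record dataframe.

    Records are tagged, encrypted, TDMA-scheduled frame by frame, sent over
    the IDOX-selected channel, and decrypted at the base station. Returns the
    delivered dataframe (identical to the input unless ``drop_on_failure``)
    and a JSONL-able event log.
    """
    rng = np.random.default_rng(seed)
    channels = channels or [Channel(id=0, noise_scale=0.1, success_prob=1.0)]
    hub_key = hub_key or HubKey(0, bytes(16))
    frame_size = frame_size or min(len(df), 16) or 1
    chosen = select_channel(channels, idox_config=idox_config, seed=seed)
    channel = next(c for c in channels if c.id == chosen)

    events: list[dict] = []
    delivered_idx: list[int] = []
    rows = list(df.iterrows())
    for start in range(0, len(rows), frame_size):
        batch = rows[start : start + frame_size]
        packets = []
        for idx, row in batch:
            payload = json.dumps({a: float(row[a]) for a in ATTRIBUTES}).encode()
            packets.append(
                Packet(
                    payload=aes.encrypt_payload(
                        payload, hub_key.key, nonce=rng.bytes(aes.NONCE_LEN)
                    ),
                    priority=classify_priority(row),
                    source=int(idx),
                )
            )
        frame = schedule_tdma(packets, frame_size)
        for slot, pkt in sorted(frame.assignments.items()):
            ok = bool(rng.random() < channel.success_prob)
            if ok or not drop_on_failure:
                aes.decrypt_payload(pkt.payload, hub_key.key)  # hub-side integrity
                delivered_idx.append(pkt.source)
            events.append(
                {
                    "frame": start // frame_size,
                    "slot": slot,
                    "node": pkt.source,
                    "priority": pkt.priority,
                    "channel": channel.id,
                    "outcome": "ok" if ok else "failed",
                }
            )
    return df.loc[sorted(delivered_idx)], events
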