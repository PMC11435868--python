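"""Software model of infrared code recording, mapping and transmission.

Consumer IR remotes modulate commands as alternating pulse/space timing
"ticks" (microseconds).  The dominant consumer scheme is the NEC
protocol: a 9 ms leader pulse, 4.5 ms space, then 32 pulse-distance-coded
bits (562.5 µs pulse followed by a 562.5 µs space for 0 or a 1687.5 µs
space for 1) and a trailing 562.5 µs burst — 67 ticks in total.  NEC is
implemented as a full codec here; Sony (12/20-bit) and RC5 (14-bit)
frames, and anything from an unrecognised manufacturer, round-trip as raw
tick recordings.

Raw recordings of unknown protocols cannot be told apart from scrambled
captures (reflections, attenuation) by inspection, so an unknown code is
accepted only when at least two independent recordings agree tick-wise
within tolerance — scrambled captures are effectively random and never
repeat.

Transmission is simulated: every send is appended to a virtual bus log
(JSON-lines), time-stamped, in place of a physical 38 kHz emitter.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

logger = logging.getLogger(__name__)

# NEC timing constants (microseconds)
NEC_LEADER_PULSE = 9000.0
NEC_LEADER_SPACE = 4500.0
NEC_BIT_PULSE = 562.5
NEC_ZERO_SPACE = 562.5
NEC_ONE_SPACE = 1687.5
NEC_TRAILER = 562.5
NEC_BITS = 32
NEC_TICKS = 2 + 2 * NEC_BITS + 1  # 67

PROTOCOL_BITS = {"NEC": 32, "SONY12": 12, "SONY20": 20, "RC5": 14}
PROTOCOLS = tuple(PROTOCOL_BITS) + ("UNKNOWN_RAW",)
REPEAT_BEHAVIOURS = ("resend_code", "dedicated_repeat_symbol")


@dataclass(frozen=True)
class IRCode:
    """One remote command: a decoded payload or a raw tick recording."""

    code_id: str
    protocol: str
    payload: Optional[int] = None
    ticks_us: Optional[tuple[float, ...]] = None
    repeat_behaviour: str = "resend_code"

    def __post_init__(self) -> None:
        if self.protocol not in PROTOCOLS:
            raise ValueError(f"unknown protocol {self.protocol!r}")
        if self.repeat_behaviour not in REPEAT_BEHAVIOURS:
            raise ValueError(f"unknown repeat behaviour {self.repeat_behaviour!r}")
        if self.protocol == "UNKNOWN_RAW":
            if self.ticks_us is None or len(self.ticks_us) < 2:
                raise ValueError("raw codes need >= 2 ticks")
            if any(t <= 0 for t in self.ticks_us):
                raise ValueError("tick durations must be positive")
            object.__setattr__(self, "ticks_us", tuple(float(t) for t in self.ticks_us))
        else:
            bits = PROTOCOL_BITS[self.protocol]
            if self.payload is None or not 0 <= self.payload < (1 << bits):
                raise ValueError(
                    f"{self.protocol} payload must be a {bits}-bit value"
                )

    def to_ticks(self) -> tuple[float, ...]:
        """Tick representation used for (simulated) transmission."""
        if self.protocol == "NEC":
            return tuple(nec_encode(self.payload))
        if self.ticks_us is not None:
            return self.ticks_us
        raise ValueError(
            f"{self.protocol} code {self.code_id!r} has no recorded ticks; "
            "only NEC payloads can be synthesised"
        )


def nec_encode(payload: int) -> list[float]:
    """Encode a 32-bit payload as a standard NEC tick frame (67 ticks).

    Bits are sent most-significant first.  Raises on out-of-range payloads.
    """
    if not 0 <= payload < (1 << NEC_BITS):
        raise ValueError("NEC payload must be in [0, 2^32)")
    ticks = [NEC_LEADER_PULSE, NEC_LEADER_SPACE]
    for bit_pos in range(NEC_BITS - 1, -1, -1):
        ticks.append(NEC_BIT_PULSE)
        ticks.append(NEC_ONE_SPACE if (payload >> bit_pos) & 1 else NEC_ZERO_SPACE)
    ticks.append(NEC_TRAILER)
    return ticks


def _within(value: float, nominal: float, tol: float) -> bool:
    return abs(value - nominal) <= tol * nominal


def nec_decode(ticks: Sequence[float], tolerance: float = 0.25) -> Optional[int]:
    """Decode an NEC tick frame; ``None`` when the frame does not match.

    Matching is tolerant to ``tolerance`` relative timing jitter on every
    tick.  Non-NEC input returns ``None`` (never raises) so the caller can
    fall through to raw recording.
    """
    if not 0 < tolerance < 0.5:
        raise ValueError("tolerance must be in (0, 0.5)")
    ticks = list(ticks)
    if len(ticks) != NEC_TICKS:
        return None
    if not (_within(ticks[0], NEC_LEADER_PULSE, tolerance)
            and _within(ticks[1], NEC_LEADER_SPACE, tolerance)):
        return None
    if not _within(ticks[-1], NEC_TRAILER, tolerance):
        return None
    payload = 0
    for i in range(NEC_BITS):
        pulse = ticks[2 + 2 * i]
        space = ticks[3 + 2 * i]
        if not _within(pulse, NEC_BIT_PULSE, tolerance):
            return None
        if _within(space, NEC_ONE_SPACE, tolerance):
            bit = 1
        elif _within(space, NEC_ZERO_SPACE, tolerance):
            bit = 0
        else:
            return None
        payload = (payload << 1) | bit
    return payload


def classify_ticks(ticks: Sequence[float], tolerance: float = 0.25) -> IRCode:
    """Decode a recording as NEC if possible, else store it raw."""
    payload = nec_decode(ticks, tolerance)
    if payload is not None:
        return IRCode(code_id="", protocol="NEC", payload=payload)
    return IRCode(code_id="", protocol="UNKNOWN_RAW", ticks_us=tuple(ticks))


def _ticks_match(a: Sequence[float], b: Sequence[float], tolerance: float) -> bool:
    if len(a) != len(b):
        return False
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    scale = np.maximum(np.abs(a), np.abs(b))
    return bool((np.abs(a - b) <= tolerance * scale).all())


def verify_unknown(
    recordings: Sequence[Sequence[float]],
    tolerance: float = 0.25,
    code_id: str = "",
) -> Optional[IRCode]:
    """Accept an unknown-protocol recording only if it repeats.

    Scrambled captures are effectively random, so two recordings agreeing
    tick-wise within tolerance indicate the true protocol pattern.  The
    largest mutually-agreeing cluster wins; its element-wise mean becomes
    the accepted raw code.  Returns ``None`` when no two recordings agree.
    """
    if len(recordings) < 2:
        raise ValueError("need at least 2 recordings to verify an unknown code")
    best_cluster: list[int] = []
    for i in range(len(recordings)):
        cluster = [i] + [
            j
            for j in range(len(recordings))
            if j != i and _ticks_match(recordings[i], recordings[j], tolerance)
        ]
        if len(cluster) > len(best_cluster):
            best_cluster = cluster
    if len(best_cluster) < 2:
        return None
    members = np.asarray([np.asarray(recordings[k], dtype=float) for k in best_cluster])
    return IRCode(
        code_id=code_id,
        protocol="UNKNOWN_RAW",
        ticks_us=tuple(members.mean(axis=0).tolist()),
    )


# ---------------------------------------------------------------------------
# Code store, gesture map, virtual bus


class CodeStore:
    """Named collection of IR codes with JSON persistence."""

    def __init__(self, codes: Sequence[IRCode] = ()) -> None:
        self._codes: dict[str, IRCode] = {}
        for code in codes:
            self.add(code)

    def add(self, code: IRCode) -> None:
        if not code.code_id:
            raise ValueError("stored codes need a non-empty code_id")
        self._codes[code.code_id] = code

    def __getitem__(self, code_id: str) -> IRCode:
        return self._codes[code_id]

    def __contains__(self, code_id: str) -> bool:
        return code_id in self._codes

    def __len__(self) -> int:
        return len(self._codes)

    def ids(self) -> list[str]:
        return list(self._codes)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        payload = []
        for code in self._codes.values():
            entry: dict = {
                "id": code.code_id,
                "protocol": code.protocol,
                "repeat_behaviour": code.repeat_behaviour,
            }
            if code.payload is not None:
                entry["payload_hex"] = f"0x{code.payload:X}"
            if code.ticks_us is not None:
                entry["ticks_us"] = list(code.ticks_us)
            payload.append(entry)
        path.write_text(json.dumps(payload, indent=2))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "CodeStore":
        entries = json.loads(Path(path).read_text())
        codes = []
        for e in entries:
            codes.append(
                IRCode(
                    code_id=e["id"],
                    protocol=e["protocol"],
                    payload=int(e["payload_hex"], 16) if "payload_hex" in e else None,
                    ticks_us=tuple(e["ticks_us"]) if "ticks_us" in e else None,
                    repeat_behaviour=e.get("repeat_behaviour", "resend_code"),
                )
            )
        return cls(codes)


class GestureMap:
    """Many-to-many mapping between gesture labels and stored code ids.

    One gesture may drive several codes (synchronous teleoperation of
    multiple devices) and several gestures may drive the same code
    (redundancy against poor recognition).
    """

    def __init__(self, mapping: dict[str, list[str]], store: CodeStore) -> None:
        for gesture, code_ids in mapping.items():
            for cid in code_ids:
                if cid not in store:
                    raise KeyError(f"gesture {gesture!r} references unknown code {cid!r}")
        self.mapping = {g: list(ids) for g, ids in mapping.items()}
        self.store = store

    def codes_for(self, gesture: str) -> list[IRCode]:
        return [self.store[cid] for cid in self.mapping.get(gesture, [])]

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.mapping, sort_keys=True))
        return path

    @classmethod
    def load(cls, path: str | Path, store: CodeStore) -> "GestureMap":
        mapping = yaml.safe_load(Path(path).read_text()) or {}
        return cls(mapping, store)


class VirtualBus:
    """Append-only transmission log standing in for the IR emitter."""

    def __init__(self, log_path: Optional[str | Path] = None) -> None:
        self.records: list[dict] = []
        self.log_path = Path(log_path) if log_path is not None else None
        if self.log_path is not None:
            self.log_path.touch()

    def transmit(self, code: IRCode, t: float, note: str = "") -> dict:
        record = {
            "t": float(t),
            "code_id": code.code_id,
            "protocol": code.protocol,
            "payload_hex": None if code.payload is None else f"0x{code.payload:X}",
            "n_ticks": len(code.to_ticks()),
            "note": note,
        }
        self.records.append(record)
        if self.log_path is not None:
            with self.log_path.open("a") as fh:
                fh.write(json.dumps(record) + "\n")
        return record

    def __len__(self) -> int:
        return len(self.records)


class IRController:
    """Drives the virtual bus from debounced decisions and controller output."""

    def __init__(self, gmap: GestureMap, bus: Optional[VirtualBus] = None) -> None:
        self.gmap = gmap
        # not `bus or ...`: an empty bus has len 0 and is falsy
        self.bus = bus if bus is not None else VirtualBus()
        self._last_index: Optional[int] = None
        self._last_repeat_t: Optional[float] = None

    def on_state_change(self, gesture: str, t: float = 0.0) -> list[dict]:
        """Transmit every code mapped to a newly active gesture, once."""
        codes = self.gmap.codes_for(gesture)
        if not codes:
            logger.warning("gesture %r has no mapped IR codes; nothing sent", gesture)
            return []
        self._last_index = None
        self._last_repeat_t = None
        return [self.bus.transmit(code, t, note="state_change") for code in codes]

    def on_controller_output(self, output, t: float = 0.0) -> list[dict]:
        """Consume a proportional-control output while a gesture is held.

        ``index_increment``: transmits the stored code at the computed
        index whenever the index changes (clamped to the stored range).
        ``repeat_rate``: re-transmits the mapped codes at the implied rate.
        Other modes transmit nothing here (discrete states are device
        interpretations of the same transmissions).
        """
        if output is None:
            self._last_index = None
            self._last_repeat_t = None
            return []
        codes = self.gmap.codes_for(output.gesture)
        if not codes:
            logger.warning(
                "gesture %r has no mapped IR codes; nothing sent", output.gesture
            )
            return []
        sent: list[dict] = []
        if output.mode == "index_increment" and output.code_index is not None:
            idx = int(np.clip(output.code_index, 0, len(codes) - 1))
            if idx != self._last_index:
                self._last_index = idx
                sent.append(self.bus.transmit(codes[idx], t, note=f"index={idx}"))
        elif output.mode == "repeat_rate" and output.repeat_hz:
            period = 1.0 / output.repeat_hz
            if self._last_repeat_t is None or t - self._last_repeat_t >= period:
                self._last_repeat_t = t
                sent.extend(
                    self.bus.transmit(code, t, note="repeat") for code in codes
                )
        return sent
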