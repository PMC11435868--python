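import json

import numpy as np
import pytest

from fmgkit import (
    CodeStore,
    GestureMap,
    IRCode,
    IRController,
    SpatialState,
    VirtualBus,
    classify_ticks,
    nec_decode,
    nec_encode,
    spatial_update,
    verify_unknown,
)
from fmgkit.ircontrol import NEC_TICKS


def test_nec_all_zero_payload_frame():
    ticks = nec_encode(0x00000000)
    assert len(ticks) == 67 == NEC_TICKS
    assert ticks[0] == 9000.0 and ticks[1] == 4500.0
    data_spaces = ticks[3:66:2]
    assert all(s == 562.5 for s in data_spaces)
    assert ticks[-1] == 562.5


def test_nec_all_one_payload_frame():
    ticks = nec_encode(0xFFFFFFFF)
    assert len(ticks) == 67
    assert all(s == 1687.5 for s in ticks[3:66:2])


def test_nec_roundtrip_on_random_payloads():
    rng = np.random.default_rng(123)
    payloads = rng.integers(0, 2 ** 32, size=1000, dtype=np.uint64)
    for p in payloads:
        assert nec_decode(nec_encode(int(p))) == int(p)


def test_nec_decode_tolerates_ten_percent_jitter():
    rng = np.random.default_rng(7)
    for p in (0xA55A00FF, 0x00000000, 0xDEADBEEF):
        ticks = np.asarray(nec_encode(p))
        jittered = ticks * rng.uniform(0.9, 1.1, size=ticks.size)
        assert nec_decode(jittered.tolist()) == p


def test_nec_decode_rejects_beyond_tolerance_monotonically():
    """Decoding survives small jitter and fails at gross jitter."""
    ticks = np.asarray(nec_encode(0x12345678))
    ok = nec_decode((ticks * 1.10).tolist(), tolerance=0.25)
    assert ok == 0x12345678
    # scaling a one-space down to zero-space territory corrupts the payload
    broken = ticks.copy()
    broken[3] = 562.5 if broken[3] > 1000 else 1687.5
    assert nec_decode(broken.tolist()) != 0x12345678


def test_random_ticks_classified_raw():
    rng = np.random.default_rng(11)
    ticks = rng.uniform(100, 5000, size=40).tolist()
    code = classify_ticks(ticks)
    assert code.protocol == "UNKNOWN_RAW"
    assert nec_decode(ticks) is None


def test_nec_payload_range_checked():
    with pytest.raises(ValueError):
        nec_encode(-1)
    with pytest.raises(ValueError):
        nec_encode(1 << 32)
    with pytest.raises(ValueError):
        nec_decode(nec_encode(0), tolerance=0.7)


def test_verify_unknown_accepts_identical_recordings():
    rec = [500.0, 1500.0, 500.0, 700.0]
    code = verify_unknown([rec, rec, rec])
    assert code is not None
    assert code.ticks_us == tuple(rec)


def test_verify_unknown_rejects_mutually_different_recordings():
    rng = np.random.default_rng(3)
    recs = [rng.uniform(100, 5000, size=30).tolist() for _ in range(3)]
    assert verify_unknown(recs) is None


def test_verify_unknown_accepts_matching_pair_over_scramble():
    rng = np.random.default_rng(4)
    true = rng.uniform(400, 2000, size=20)
    a = (true * rng.uniform(0.95, 1.05, 20)).tolist()
    b = (true * rng.uniform(0.95, 1.05, 20)).tolist()
    scrambled = rng.uniform(100, 5000, size=20).tolist()
    code = verify_unknown([a, scrambled, b])
    assert code is not None
    np.testing.assert_allclose(code.ticks_us, (np.asarray(a) + b) / 2)
    with pytest.raises(ValueError):
        verify_unknown([a])


def test_ircode_validation():
    with pytest.raises(ValueError):
        IRCode("x", "NEC", payload=1 << 32)
    with pytest.raises(ValueError):
        IRCode("x", "SONY12", payload=1 << 12)
    with pytest.raises(ValueError):
        IRCode("x", "UNKNOWN_RAW", ticks_us=(100.0,))
    with pytest.raises(ValueError):
        IRCode("x", "UNKNOWN_RAW", ticks_us=(100.0, -5.0))
    sony = IRCode("x", "SONY12", payload=0x5A5, ticks_us=(100.0, 200.0))
    assert sony.to_ticks() == (100.0, 200.0)


def demo_map(n_codes=2, gesture="Fist"):
    codes = [IRCode(f"c{i}", "NEC", payload=i) for i in range(n_codes)]
    store = CodeStore(codes)
    return GestureMap({gesture: [f"c{i}" for i in range(n_codes)]}, store)


def test_state_change_transmits_every_mapped_code_once():
    controller = IRController(demo_map(2))
    sent = controller.on_state_change("Fist", t=0.0)
    assert len(sent) == 2
    assert len(controller.bus) == 2


def test_repeated_gesture_transmits_nothing_more():
    from fmgkit import debounce
    controller = IRController(demo_map(2))
    previous = None
    for decision in ["Fist", "Fist", "Fist"]:
        if debounce(previous, decision):
            controller.on_state_change(decision)
        previous = decision
    assert len(controller.bus) == 2  # only the first activation fired


def test_index_increment_crossing_two_boundaries():
    gmap = demo_map(3)
    controller = IRController(gmap)
    state = SpatialState(default_axis="roll", mode="index_increment",
                         gain=1.0, step_deg=10.0)
    spatial_update(state, "Fist", np.array([0.0, 0.0, 0.0]))
    transmitted = []
    for angle in [0.0, 12.0, 25.0]:
        out = spatial_update(state, "Fist", np.array([0.0, 0.0, angle]))
        transmitted += controller.on_controller_output(out, t=angle)
    assert [r["code_id"] for r in transmitted] == ["c0", "c1", "c2"]
    # indices 1 then 2 follow the two step-boundary crossings
    assert [r["note"] for r in transmitted[1:]] == ["index=1", "index=2"]


def test_repeat_rate_mode_respects_rate():
    gmap = demo_map(1)
    controller = IRController(gmap)
    state = SpatialState(default_axis="roll", mode="repeat_rate", gain=1.0,
                         rate_scale=0.1)  # 20 deg -> 2 codes/s
    spatial_update(state, "Fist", np.array([0.0, 0.0, 0.0]))
    sent = []
    for t in np.arange(0.0, 2.01, 0.25):  # exact binary increments
        out = spatial_update(state, "Fist", np.array([0.0, 0.0, 20.0]))
        sent += controller.on_controller_output(out, t=float(t))
    assert len(sent) == 5  # t = 0.0, 0.5, 1.0, 1.5, 2.0


def test_unmapped_gesture_is_a_warning_noop(caplog):
    controller = IRController(demo_map(1, gesture="Fist"))
    with caplog.at_level("WARNING"):
        sent = controller.on_state_change("Pinch")
    assert sent == []
    assert "no mapped IR codes" in caplog.text


def test_store_map_and_bus_persistence(tmp_path):
    codes = [
        IRCode("tv_power", "NEC", payload=0x20DF10EF),
        IRCode("amp_vol", "UNKNOWN_RAW", ticks_us=(500.0, 1500.0, 500.0)),
    ]
    store = CodeStore(codes)
    store.save(tmp_path / "codes.json")
    back = CodeStore.load(tmp_path / "codes.json")
    assert back["tv_power"].payload == 0x20DF10EF
    assert back["amp_vol"].ticks_us == (500.0, 1500.0, 500.0)

    gmap = GestureMap({"Fist": ["tv_power", "amp_vol"]}, back)
    gmap.save(tmp_path / "map.yaml")
    gmap2 = GestureMap.load(tmp_path / "map.yaml", back)
    assert [c.code_id for c in gmap2.codes_for("Fist")] == ["tv_power", "amp_vol"]
    with pytest.raises(KeyError):
        GestureMap({"Fist": ["nope"]}, back)

    bus = VirtualBus(tmp_path / "bus.jsonl")
    bus.transmit(back["tv_power"], t=1.0)
    bus.transmit(back["amp_vol"], t=2.0)
    lines = (tmp_path / "bus.jsonl").read_text().splitlines()
    assert len(lines) == 2
    assert json.loads(lines[0])["code_id"] == "tv_power"
    assert json.loads(lines[1])["n_ticks"] == 3
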