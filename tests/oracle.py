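"""Literal-loop reference implementations of the time-domain features.

Deliberately written as plain Python summation loops, independent of the
vectorised production code, so the two can cross-check each other.
"""

import math


def oracle_features(x, eps_zc=0.0, eps_ssc=0.0, eps_wamp=0.0, eps_myop=0.0):
    w = len(x)
    iav = 0.0
    for v in x:
        iav += abs(v)
    wl = 0.0
    for i in range(w - 1):
        wl += abs(x[i + 1] - x[i])
    ssi = 0.0
    for v in x:
        ssi += v * v
    mean = sum(x) / w
    var = 0.0
    for v in x:
        var += (v - mean) ** 2
    var /= w - 1

    ssc = 0
    for i in range(1, w - 1):
        d1 = x[i] - x[i - 1]
        d2 = x[i] - x[i + 1]
        if d1 * d2 > 0 and max(abs(d1), abs(d2)) >= max(eps_ssc, 1e-300):
            ssc += 1

    zc = 0
    for i in range(w - 1):
        if x[i] * x[i + 1] < 0 and abs(x[i] - x[i + 1]) >= eps_zc:
            zc += 1

    wamp = 0
    for i in range(w - 1):
        if abs(x[i + 1] - x[i]) > eps_wamp:
            wamp += 1

    myop = 0
    for v in x:
        if abs(v) > eps_myop:
            myop += 1

    dasdv_sum = 0.0
    for i in range(w - 1):
        dasdv_sum += (x[i + 1] - x[i]) ** 2

    mav1 = 0.0
    for i in range(1, w + 1):
        weight = 1.0 if 0.25 * w <= i <= 0.75 * w else 0.5
        mav1 += weight * abs(x[i - 1])
    mav1 /= w

    mav2 = 0.0
    for i in range(1, w + 1):
        if i < 0.25 * w:
            weight = 4.0 * i / w
        elif i > 0.75 * w:
            weight = 4.0 * (w - i) / w
        else:
            weight = 1.0
        mav2 += weight * abs(x[i - 1])
    mav2 /= w

    def tm(k):
        total = 0.0
        for v in x:
            total += v ** k
        return abs(total / w)

    return {
        "IAV": iav,
        "WL": wl,
        "AAC": wl / w,
        "SSC": float(ssc),
        "SSI": ssi,
        "RMS": math.sqrt(ssi / w),
        "VAR": var,
        "MAV": iav / w,
        "MAV1": mav1,
        "MAV2": mav2,
        "ZC": float(zc),
        "TM3": tm(3),
        "TM4": tm(4),
        "TM5": tm(5),
        "WAMP": float(wamp),
        "DASDV": math.sqrt(dasdv_sum / (w - 1)),
        "MYOP": myop / w,
    }
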