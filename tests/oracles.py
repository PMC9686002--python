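"""Independent brute-force oracles for per-epoch HRV statistics.

Deliberately written with plain Python loops and ``math`` only, so they
share no code path with the package implementation they check.
"""

import math


def oracle_time_domain(intervals):
    iv = list(map(float, intervals))
    n = len(iv)
    diffs = [iv[i + 1] - iv[i] for i in range(n - 1)]
    adiffs = [abs(d) for d in diffs]
    hr = [60000.0 / x for x in iv]

    def mean(xs):
        return sum(xs) / len(xs)

    def sample_sd(xs):
        if len(xs) < 2:
            return 0.0
        m = mean(xs)
        return math.sqrt(sum((x - m) ** 2 for x in xs) / (len(xs) - 1))

    nn50 = sum(1 for d in adiffs if d > 50.0)
    nn20 = sum(1 for d in adiffs if d > 20.0)
    return {
        "rri_min": min(iv),
        "rri_max": max(iv),
        "rri_mean": mean(iv),
        "rri_count": float(n),
        "rridiff_mean": mean(adiffs),
        "rridiff_min": min(adiffs),
        "rridiff_max": max(adiffs),
        "hr_mean": mean(hr),
        "hr_min": min(hr),
        "hr_max": max(hr),
        "hr_sd": sample_sd(hr),
        "sdnn": sample_sd(iv),
        "rmssd": math.sqrt(mean([d**2 for d in diffs])),
        "sdsd": sample_sd(diffs),
        "nn50": float(nn50),
        "pnn50": 100.0 * nn50 / len(diffs),
        "nn20": float(nn20),
        "pnn20": 100.0 * nn20 / len(diffs),
    }


def oracle_poincare(intervals):
    iv = list(map(float, intervals))
    x = iv[:-1]
    y = iv[1:]
    d = [(b - a) / math.sqrt(2.0) for a, b in zip(x, y)]
    s = [(b + a) / math.sqrt(2.0) for a, b in zip(x, y)]
    sd1 = math.sqrt(sum(v**2 for v in d) / len(d))  # uncentred second moment
    ms = sum(s) / len(s)
    sd2 = math.sqrt(sum((v - ms) ** 2 for v in s) / len(s))  # population SD
    return {
        "sd1": sd1,
        "sd2": sd2,
        "sd_ratio": sd1 / sd2 if sd2 > 0 else math.nan,
        "ellipse_area": math.pi * sd1 * sd2,
    }
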