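"""Published strain-level summary tables for the yeast alpha-synuclein study.

These (mean, SD, n) summaries are the inputs of the statistics stage when
raw recordings are unavailable: growth half-times t50 (hours) and
Rest/Peak [Ca2+] (micromolar) per strain/condition.
"""

from __future__ import annotations

from .stats import GroupSummary

#: growth t50 (hours), LRB906 background at 25 C
GROWTH_T50_LRB906 = {
    "LRB906": GroupSummary("LRB906", 29.97, 2.99, 10),
    "LRB906+a-syn": GroupSummary("LRB906+a-syn", 42.27, 5.84, 16),
    "sec4ts": GroupSummary("sec4ts", 42.50, 1.44, 11),
    "sec4ts+a-syn": GroupSummary("sec4ts+a-syn", 56.63, 4.81, 11),
    "LRB906-pSEC4": GroupSummary("LRB906-pSEC4", 27.19, 1.50, 9),
    "LRB906-pSEC4+a-syn": GroupSummary("LRB906-pSEC4+a-syn", 35.16, 3.72, 12),
}

#: growth t50 (hours), BY4741 background
GROWTH_T50_BY4741 = {
    "BY4741": GroupSummary("BY4741", 21.60, 2.35, 13),
    "BY4741+a-syn": GroupSummary("BY4741+a-syn", 32.52, 4.11, 13),
    "BY4741-pPMC1": GroupSummary("BY4741-pPMC1", 22.25, 2.52, 13),
    "BY4741-pPMC1+a-syn": GroupSummary("BY4741-pPMC1+a-syn", 26.53, 6.26, 12),
    "pmc1": GroupSummary("pmc1", 25.12, 2.29, 14),
    "pmc1+a-syn": GroupSummary("pmc1+a-syn", 36.00, 6.25, 13),
    "vcx1": GroupSummary("vcx1", 24.71, 1.70, 6),
    "vcx1+a-syn": GroupSummary("vcx1+a-syn", 38.32, 8.03, 9),
}

#: Rest [Ca2+] (micromolar), LRB906 background at 37 C
REST_CA_LRB906 = {
    "LRB906": GroupSummary("LRB906", 0.00, 0.20, 24),
    "LRB906+a-syn": GroupSummary("LRB906+a-syn", 0.29, 0.12, 33),
    "sec4ts": GroupSummary("sec4ts", 0.12, 0.20, 35),
    "sec4ts+a-syn": GroupSummary("sec4ts+a-syn", 0.53, 0.26, 38),
}

#: Peak [Ca2+] (micromolar), LRB906 background at 37 C
PEAK_CA_LRB906 = {
    "LRB906": GroupSummary("LRB906", 1.33, 0.28, 24),
    "LRB906+a-syn": GroupSummary("LRB906+a-syn", 2.07, 0.29, 33),
    "sec4ts": GroupSummary("sec4ts", 3.21, 0.66, 35),
    "sec4ts+a-syn": GroupSummary("sec4ts+a-syn", 3.71, 0.53, 38),
}

#: Rest/Peak [Ca2+] (micromolar), BY4741 background at 30 C
REST_CA_BY4741 = {
    "BY4741": GroupSummary("BY4741", 0.12, 0.14, 41),
    "BY4741+a-syn": GroupSummary("BY4741+a-syn", 0.26, 0.17, 25),
    "pmc1": GroupSummary("pmc1", 0.19, 0.10, 25),
    "vcx1": GroupSummary("vcx1", 0.05, 0.10, 26),
    "vcx1+a-syn": GroupSummary("vcx1+a-syn", 0.12, 0.15, 27),
}

PEAK_CA_BY4741 = {
    "BY4741": GroupSummary("BY4741", 1.34, 0.21, 41),
    "BY4741+a-syn": GroupSummary("BY4741+a-syn", 2.51, 0.23, 25),
    "pmc1": GroupSummary("pmc1", 0.94, 0.22, 25),
    "vcx1": GroupSummary("vcx1", 1.39, 0.11, 26),
    "vcx1+a-syn": GroupSummary("vcx1+a-syn", 2.25, 0.15, 27),
}
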