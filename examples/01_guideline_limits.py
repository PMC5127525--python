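"""Print every ICNIRP/IEEE basic restriction at the 150 kHz WPT frequency.

The limits protect against nerve electrostimulation (J, E99, E5mm) and
tissue heating (SAR); the E5mm limits differ by tissue group.
"""

from qsdose import limit

CASES = [
    ("ICNIRP1998", "J", None),
    ("ICNIRP2010", "E99", None),
    ("IEEE", "E5mm", "brain"),
    ("IEEE", "E5mm", "heart"),
    ("IEEE", "E5mm", "limbs"),
    ("IEEE", "E5mm", "other"),
    ("IEEE", "SAR_10g", "head_trunk"),
    ("IEEE", "SAR_10g", "limbs"),
    ("IEEE", "SAR_wm", None),
]

print(f"{'guideline':<11} {'metric':<8} {'group':<11} {'limit':>12}  units")
for guideline, metric, group in CASES:
    lim = limit(guideline, metric, 150e3, group)
    print(
        f"{lim.guideline:<11} {lim.metric:<8} {(lim.group or ''):<11} "
        f"{lim.value:>12.6g}  {lim.units}"
    )
print(
    "\nEach row is the general-public basic restriction at 150 kHz; a dose "
    "report is compliant when every computed metric stays below its row."
)
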