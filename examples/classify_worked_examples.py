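"""Image-level FISH arithmetic on published per-image worked examples.

Each line takes the per-image average HER2 copy number and average CEP17
copy number (copies/nucleus), derives the HER2/CEP17 ratio, and assigns
the 2018 ASCO/CAP five-group amplification status.  Group 1 is classically
amplified (ratio >= 2 and >= 4 HER2 copies); Group 5 is not amplified.
"""

from her2fish import classify_group, her2_cep17_ratio

examples = [
    ("amplified image", 13.80, 2.60),
    ("equivocal-regime image", 4.08, 2.75),
    ("non-amplified image", 3.20, 2.21),
]

for name, avg_her2, avg_cep17 in examples:
    ratio = her2_cep17_ratio(avg_her2, avg_cep17)
    group = classify_group(avg_her2, ratio)
    print(
        f"{name}: avg HER2 {avg_her2:.2f}, avg CEP17 {avg_cep17:.2f} "
        f"-> ratio {ratio:.2f} -> ASCO/CAP group {int(group)}"
    )
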