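"""Build the Glc-GA candidate mass-channel table from the GA registry.

Each registered gibberellin is glucosylated (+C6H10O5), amidated with DMED
(+C4H12N2 -H2O), protonated, and shifted by the d4 label (+4.0251 Da) to
give its (light, heavy) extraction channel; isobaric GAs share a channel.
"""

from glcga import build_channels
from glcga.candidate_db import channels_to_frame
from glcga.synth_data import builtin_registry

channels = build_channels(builtin_registry())
frame = channels_to_frame(channels)
print(frame.to_string(index=False, max_colwidth=48))
print(
    f"\n{len(frame)} channels from {sum(len(c.members) for c in channels)} candidate "
    "Glc-GAs.  light_mz/heavy_mz are the DMED / d4-DMED [M+H]+ values used "
    "for extracted-ion-chromatogram screening; members are isobaric parents."
)
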