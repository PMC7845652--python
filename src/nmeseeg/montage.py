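"""Electrode montage used by the recording setup.

32 EEG channels of the international 10/20 system (actiCAP layout) plus two
bipolar muscle sensors on the stimulated forearm. The region of interest
covers the sensorimotor cortex contralateral to the stimulated (right) limb.
"""

EEG_CHANNELS: tuple[str, ...] = (
    "FP1", "FP2", "F7", "F3", "Fz", "F4", "F8",
    "FC3", "FC1", "FCz", "FC2", "FC4",
    "C5", "C3", "C1", "Cz", "C2", "C4", "C6",
    "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6",
    "P7", "P3", "P4", "P8", "O1", "O2",
)

EMG_CHANNELS: tuple[str, ...] = ("EMG1", "EMG2")

#: Channels over the hand/forearm representation of the left sensorimotor
#: cortex (contralateral to right-forearm stimulation).
ROI_CHANNELS: tuple[str, ...] = ("C3", "C1", "CP3", "CP1")
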