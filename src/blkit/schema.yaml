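# Property-name schema for the time-aligned brain-behavior HDF5 format.
# Users may extend this vocabulary with a custom schema file of the same shape;
# names not listed here raise validator *warnings*, never errors.

# Valid dataset names inside a group's `props` subgroup.
group_properties:
  - title
  - type
  - samplingRate
  - channelNames
  - unit
  - description

# Controlled vocabulary for the required `type` property: either a brain
# recording modality or a behavior/stimulus kind. Extensible; unknown values
# are warnings.
types:
  - fMRI
  - ECoG
  - EEG
  - MEG
  - spikes
  - stimulus
  - physicalMovement
  - behavior
  - eyeTracking
  - audio

# Valid dataset names inside the root `fileHeader` group.
file_header_properties:
  - experimentDescription
  - species
  - subjectId
  - subjectAge
  - subjectSex
  - lab
  - experimenter
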