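# Default experiment configuration.
#
# The schedule block is the measurement log of the physical experiment this
# pipeline emulates: per-scanner tank water volume (L), background activity at
# each session start (MBq) and acquisition time (s) for the three sequential
# lesion sessions. The settings block is the eight-entry reconstruction
# registry; psf_fwhm values are effective-resolution assumptions (mm), not
# measured values. voxel_size is (z, y, x) in mm.

lesions: [L1, L2, L3]
seed: 0
base_dwell_s: 2.0
fine_spacing_mm: 1.0
bin_width_suv: 0.3125   # FBS parameter B
bin_count: 64           # FBN parameter D
resampling_mm: [native] # add 1.0, 2.5, 3.0, 4.0 for the resampling study
reference_setting: D

settings:
  A: {scanner_name: Siemens Biograph TruePoint 64, voxel_size: [2.67, 2.67, 2.67], psf_fwhm: 5.5, postfilter_fwhm: 5.0, noise_scale: 0.30}
  B: {scanner_name: Siemens Biograph TruePoint 64, voxel_size: [3.0, 4.0, 4.0], psf_fwhm: 6.0, postfilter_fwhm: 5.0, noise_scale: 0.30}
  C: {scanner_name: Mediso AnyScan PET/CT, voxel_size: [3.0, 3.0, 3.0], psf_fwhm: 6.0, postfilter_fwhm: 0.0, noise_scale: 0.28}
  D: {scanner_name: GE Discovery IQ, voxel_size: [2.73, 2.73, 2.73], psf_fwhm: 6.3, postfilter_fwhm: 6.4, noise_scale: 0.25}
  E: {scanner_name: GE Discovery IQ, voxel_size: [3.64, 3.64, 3.64], psf_fwhm: 6.5, postfilter_fwhm: 4.4, noise_scale: 0.27}
  F: {scanner_name: Philips Gemini TF 64, voxel_size: [4.0, 4.0, 4.0], psf_fwhm: 5.2, postfilter_fwhm: 0.0, noise_scale: 0.30}
  G: {scanner_name: GE Discovery MI, voxel_size: [2.73, 2.73, 2.73], psf_fwhm: 4.0, postfilter_fwhm: 0.0, noise_scale: 0.20}
  H: {scanner_name: GE Discovery MI, voxel_size: [2.73, 2.73, 2.73], psf_fwhm: 4.4, postfilter_fwhm: 3.2, noise_scale: 0.22}

schedule:
  Siemens Biograph TruePoint 64:
    volume_l: 15.1
    initial_activity_mbq: [87.2, 70.8, 55.8]
    acquisition_time_s: [1730, 1883, 2600]
    time_inaccuracy_s: [-20, -1, -18]
  Mediso AnyScan PET/CT:
    volume_l: 15.0
    initial_activity_mbq: [88.5, 72.6, 57.6]
    acquisition_time_s: [1730, 1883, 2600]
    time_inaccuracy_s: [-20, -10, -8]
  GE Discovery IQ:
    volume_l: 15.2
    initial_activity_mbq: [88.1, 71.9, 57.1]
    acquisition_time_s: [1730, 1883, 2600]
    time_inaccuracy_s: [-4, -4, -4]
  Philips Gemini TF 64:
    volume_l: 15.0
    initial_activity_mbq: [89.4, 72.5, 58.1]
    acquisition_time_s: [1730, 1883, 2600]
    time_inaccuracy_s: [-8, -10, -6]
  GE Discovery MI:
    volume_l: 15.0
    initial_activity_mbq: [89.7, 73.3, 59.1]
    acquisition_time_s: [1730, 1883, 2600]
    time_inaccuracy_s: [-9, -7, -2]
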