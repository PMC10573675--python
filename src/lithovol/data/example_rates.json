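{
  "comment": "ILLUSTRATIVE ablation-rate calibration for tests and demos only. These speeds are round numbers, not measured values; supply your own calibration for any real planning.",
  "entries": [
    {
      "laser_source": "HoYAG",
      "fiber_diameter_um": 272,
      "composition": "COM",
      "pulse_energy_J": 0.8,
      "frequency_Hz": 10,
      "ablation_speed_mm3_per_s": 1.0
    },
    {
      "laser_source": "HoYAG_MOSES",
      "fiber_diameter_um": 272,
      "composition": "COM",
      "pulse_energy_J": 0.8,
      "frequency_Hz": 10,
      "ablation_speed_mm3_per_s": 1.5
    },
    {
      "laser_source": "TFL",
      "fiber_diameter_um": 272,
      "composition": "COM",
      "pulse_energy_J": 0.5,
      "frequency_Hz": 20,
      "ablation_speed_mm3_per_s": 2.5
    },
    {
      "laser_source": "TFL",
      "fiber_diameter_um": 200,
      "composition": "uric_acid",
      "pulse_energy_J": 0.5,
      "frequency_Hz": 20,
      "ablation_speed_mm3_per_s": 3.0
    }
  ]
}
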