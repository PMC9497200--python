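# Default CTC and tdEV linear gates, values as printed in the source
# instrument gate table.  Operators: "<=" inclusive, ">" strict.
gates:
  - name: ctc
    predicates:
      - {feature: mean_intensity, channel: cd45, op: "<=", threshold: 5, units: AU}
      - {feature: mean_intensity, channel: dapi, op: ">", threshold: 45, units: AU}
      - {feature: mean_intensity, channel: ck, op: ">", threshold: 60, units: AU}
      - {feature: size, channel: ck, op: ">", threshold: 16, units: um2}
      - {feature: size, channel: ck, op: "<=", threshold: 400, units: um2}
      - {feature: overlay_ck_dapi, channel: ck, op: ">", threshold: 0.2, units: AU}
      - {feature: mean_intensity, channel: m1, op: "<=", threshold: 5, units: AU}
      - {feature: mean_intensity, channel: m2, op: "<=", threshold: 5, units: AU}
  - name: tdev
    predicates:
      - {feature: mean_intensity, channel: cd45, op: "<=", threshold: 5, units: AU}
      - {feature: mean_intensity, channel: dapi, op: "<=", threshold: 5, units: AU}
      - {feature: mean_intensity, channel: ck, op: ">", threshold: 60, units: AU}
      - {feature: max_intensity, channel: ck, op: ">", threshold: 90, units: AU}
      - {feature: area, channel: ck, op: "<=", threshold: 150, units: um2}
      - {feature: eccentricity, channel: ck, op: "<=", threshold: 0.8, units: AU}
      - {feature: perimeter_to_area, channel: ck, op: "<=", threshold: 1, units: AU}
      - {feature: perimeter, channel: ck, op: ">", threshold: 5, units: pixels}
      - {feature: size, channel: ck, op: "<=", threshold: 150, units: um2}
      - {feature: mean_intensity, channel: m1, op: "<=", threshold: 5, units: AU}
      - {feature: mean_intensity, channel: m2, op: "<=", threshold: 5, units: AU}
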