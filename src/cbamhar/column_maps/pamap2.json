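{
  "description": "Column layout of the UCI Pamap2 per-subject .dat files (space separated, 54 columns, 100 Hz). Offsets are 0-based within each 17-column IMU block.",
  "n_columns": 54,
  "timestamp_col": 0,
  "activity_col": 1,
  "heart_rate_col": 2,
  "imu_blocks": {"hand": 3, "chest": 20, "ankle": 37},
  "imu_block_offsets": {
    "temperature": [0],
    "acc_16g": [1, 2, 3],
    "acc_6g": [4, 5, 6],
    "gyro": [7, 8, 9],
    "mag": [10, 11, 12],
    "orientation": [13, 14, 15, 16]
  },
  "protocol_activities": [
    {"id": 1, "name": "lying"},
    {"id": 2, "name": "sitting"},
    {"id": 3, "name": "standing"},
    {"id": 4, "name": "walking"},
    {"id": 5, "name": "running"},
    {"id": 6, "name": "cycling"},
    {"id": 7, "name": "nordic_walking"},
    {"id": 12, "name": "ascending_stairs"},
    {"id": 13, "name": "descending_stairs"},
    {"id": 16, "name": "vacuum_cleaning"},
    {"id": 17, "name": "ironing"},
    {"id": 24, "name": "rope_jumping"}
  ],
  "native_rate_hz": 100
}
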