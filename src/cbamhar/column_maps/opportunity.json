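{
  "description": "Column layout of the UCI Opportunity per-run .dat files (space separated, 250 columns, 30 Hz). Columns are 1-based as in the dataset's column_names.txt. Each upper-body IMU block is 13 columns (acc xyz, gyro xyz, mag xyz, quaternion x4); only the first 9 are motion signals.",
  "n_columns": 250,
  "timestamp_col": 1,
  "imu_blocks": {"back": 38, "rua": 51, "rla": 64, "lua": 77, "lla": 90},
  "imu_signal_offsets": [0, 1, 2, 3, 4, 5, 6, 7, 8],
  "gesture_label_col": 250,
  "gestures": [
    {"code": 0, "name": "null"},
    {"code": 406516, "name": "open_door_1"},
    {"code": 406517, "name": "open_door_2"},
    {"code": 404516, "name": "close_door_1"},
    {"code": 404517, "name": "close_door_2"},
    {"code": 406520, "name": "open_fridge"},
    {"code": 404520, "name": "close_fridge"},
    {"code": 406505, "name": "open_dishwasher"},
    {"code": 404505, "name": "close_dishwasher"},
    {"code": 406519, "name": "open_drawer_1"},
    {"code": 404519, "name": "close_drawer_1"},
    {"code": 406511, "name": "open_drawer_2"},
    {"code": 404511, "name": "close_drawer_2"},
    {"code": 406508, "name": "open_drawer_3"},
    {"code": 404508, "name": "close_drawer_3"},
    {"code": 408512, "name": "clean_table"},
    {"code": 407521, "name": "drink_from_cup"},
    {"code": 405506, "name": "toggle_switch"}
  ],
  "native_rate_hz": 30
}
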