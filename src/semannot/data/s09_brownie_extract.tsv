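A	00:00.000	00:03.198	open-cupboard_tl
A	00:03.198	00:04.616	take-brownie_box-cupboard_tl
A	00:04.616	00:05.456	close-cupboard_tl
A	00:05.456	00:10.735	other
A	00:10.735	00:12.006	put-brownie_box-counter
A	00:12.006	00:13.941	open-cupboard_tr
A	00:13.941	00:17.044	take-bowl-cupboard_tr
A	00:17.044	00:18.522	put-bowl-counter
A	00:18.522	00:20.540	take-measuring_cup_s-cupboard_tr
A	00:20.540	00:21.571	put-measuring_cup_s-counter
A	00:21.571	00:24.704	take-measuring_cup_l-cupboard_tr
A	00:24.704	00:25.682	put-measuring_cup_l-counter
A	00:25.682	00:26.708	close-cupboard_tr
A	00:26.708	00:29.379	open-cupboard_br
A	00:29.379	00:30.412	take-oil_bottle-cupboard_br
A	00:30.412	00:31.313	close-cupboard_br
A	00:31.313	00:32.758	put-oil_bottle-counter
A	00:32.758	00:35.519	other
A	00:35.519	00:36.784	take-brownie_box-counter
A	00:36.784	00:39.069	other
A	00:39.069	00:40.044	put-brownie_box-counter
A	00:40.044	00:41.175	walk-counter_place-fridge_place
A	00:41.175	00:42.547	open-fridge
A	00:42.547	00:43.660	open-egg_box
A	00:43.660	00:45.432	take-1-egg_shell-egg_box
A	00:45.432	00:46.697	take-1-egg_shell-egg_box
A	00:46.697	00:47.296	close-egg_box
A	00:47.296	00:48.724	close-fridge
A	00:48.724	00:50.082	walk-fridge_place-counter_place
A	00:50.082	00:50.946	put-2-egg_shell-counter
A	00:50.946	00:52.502	take-1-egg_shell-counter
A	00:52.502	00:54.224	open-egg_shell
A	00:54.224	00:56.411	fill-egg-open_egg_shell-bowl
A	00:56.411	00:57.910	put-1-empty_egg_shell-sink
A	00:57.910	00:58.976	take-1-egg_shell-counter
A	00:58.976	00:58.980	take-1-egg_shell-counter
A	00:58.980	01:00.668	open-egg_shell
A	01:00.668	01:03.167	fill-egg-open_egg_shell-bowl
A	01:03.167	01:05.817	put-1-empty_egg_shell-sink
A	01:05.817	01:08.000	walk-counter_place-fridge_place
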